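"""End-to-end pipeline: simulate/load -> mine -> classify -> group -> analyse.

All randomness flows from the single config seed through a documented
derivation (proteome = seed, abEH-tree bootstrap = seed+1, LEH-tree
bootstrap = seed+2, chromatograms = seed+3), so a rerun with the same
config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ehmine import synthetic_data as sd
from ehmine.sequence_io import GeneDatabase, compile_database
from ehmine.alignment import DEFAULT_PARAMS, AlignmentParams, progressive_msa
from ehmine.mining import (DEFAULT_KEYWORDS, textmine, scan_database,
                           merge_candidates, candidates_tsv)
from ehmine.classification import (ReferenceSet, load_default_references,
                                   default_profiles, classify_candidates,
                                   classification_tsv)
from ehmine.phylo import (identity_matrix, bootstrap_supports, write_newick,
                          assign_groups)
from ehmine.mining import scan_domain
from ehmine import biotransform as bt

logger = logging.getLogger(__name__)

# Demonstration biotransformation panel emitted by `simulate`: a styrene
# oxide screen of three enzymes with known regiochemical behaviour.
DEMO_SAMPLES = [
    sd.SampleSpec("enzA", "(R)-styrene_oxide", {"S": 5.7, "R": 0.1}, 0.2, 3),
    sd.SampleSpec("enzA", "(S)-styrene_oxide", {"R": 5.5, "S": 0.1}, 0.2, 3),
    sd.SampleSpec("enzB", "(R)-styrene_oxide", {"R": 5.2, "S": 0.9}, 0.2, 3),
    sd.SampleSpec("enzB", "(S)-styrene_oxide", {"S": 8.3, "R": 0.3}, 0.2, 3),
    sd.SampleSpec("enzC", "cyclohexene_oxide", {"1R,2R": 2.0, "1S,2S": 0.13}, 0.1, 2),
]
DEMO_CONFIGS = {"(R)-styrene_oxide": "R", "(S)-styrene_oxide": "S",
                "cyclohexene_oxide": "meso"}
DEMO_LINE = (2.0, 1.0)  # slope, intercept


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    outdir: str = "ehmine_out"
    seed: int = sd.DEFAULT_SEED
    synthetic: dict | None = None          # ProteomeSpec kwargs (minus seed)
    proteomes: list[dict] = field(default_factory=list)  # {path, organism}
    keywords: list[str] = field(default_factory=lambda: list(DEFAULT_KEYWORDS))
    bootstrap_reps: int = 500
    min_support: float = 50.0
    s0: float = 10.0
    strip_nterm: bool = False
    chromatograms: str | None = None       # CSV path or "synthetic"
    substrate_configs: dict[str, str] = field(default_factory=dict)
    gap_open: float = DEFAULT_PARAMS.gap_open
    gap_extend: float = DEFAULT_PARAMS.gap_extend

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.synthetic is None and not self.proteomes:
            self.synthetic = {}
        for rec in self.proteomes:
            if not Path(rec["path"]).exists():
                raise FileNotFoundError(rec["path"])
        if self.chromatograms not in (None, "synthetic") \
                and not Path(self.chromatograms).exists():
            raise FileNotFoundError(self.chromatograms)

    @property
    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(gap_open=self.gap_open, gap_extend=self.gap_extend)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (outdir excluded)."""
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_database(config: RunConfig):
    if config.proteomes:
        db = compile_database([(r["path"], r.get("organism", "")) for r in config.proteomes])
        return db, None
    spec = sd.ProteomeSpec(seed=config.seed, **(config.synthetic or {}))
    db, manifest = sd.make_proteome(spec)
    return db, manifest


def _strip_nterm(seq: str, ehn_profile) -> str:
    hit = scan_domain(seq, ehn_profile)
    if hit is not None and hit.start <= len(seq) / 2 and hit.end < len(seq):
        return seq[hit.end:]
    return seq


def _family_tree(tag: str, members: dict[str, str], ref_groups: dict[str, str],
                 config: RunConfig, outdir: Path, seed: int, summary: dict) -> None:
    if len(members) < 4:
        summary[f"tree_{tag}"] = f"skipped ({len(members)} sequences < 4)"
        return
    ids = sorted(members)
    seqs = [members[i] for i in ids]
    idm = identity_matrix(ids, seqs, config.alignment_params)
    idm.write_tsv(outdir / f"identity_{tag}.tsv")
    rows = progressive_msa(seqs, config.alignment_params)
    tree, supports = bootstrap_supports(ids, rows, n_reps=config.bootstrap_reps,
                                        seed=seed)
    (outdir / f"tree_{tag}.nwk").write_text(write_newick(tree) + "\n")
    groups = assign_groups(tree, ref_groups, min_support=config.min_support)
    groups.write_tsv(outdir / f"groups_{tag}.tsv")
    summary[f"tree_{tag}"] = "ok"
    summary[f"groups_{tag}"] = _count(groups.labels.values())


def _count(values) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items()))


def run_pipeline(config: RunConfig, refs: ReferenceSet | None = None) -> dict:
    """Execute every stage and write the report files into ``config.outdir``.

    Returns the machine-readable summary (also written as
    ``summary.json``).  Raises on missing inputs before any stage runs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = refs or load_default_references()
    profiles = default_profiles()
    params = config.alignment_params
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    logger.info("pipeline start: seed=%d hash=%s", config.seed, summary["config_hash"])

    db, manifest = _build_database(config)
    summary["n_gene_products"] = len(db)
    if manifest is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    text_hits = textmine(db, config.keywords)
    domain_hits = scan_database(db, list(profiles.values()))
    candidates = merge_candidates(text_hits, domain_hits, db)
    candidates_tsv(candidates, db, outdir / "candidates.tsv")
    summary["n_candidates"] = len(candidates)
    summary["n_annotation_hits"] = len(text_hits)
    summary["n_domain_hits"] = len(domain_hits)

    classify_candidates(candidates, db, refs, profiles["EH-N"], params)
    classification_tsv(candidates, outdir / "classification.tsv")
    summary["families"] = _count(c.family for c in candidates)

    leh_members = {c.id: db[c.id].sequence for c in candidates if c.family == "LEH"}
    for r in refs.by_family("LEH"):
        leh_members[r.id] = r.sequence
    ab_members = {}
    for c in candidates:
        if c.family in ("abEH_Nterm", "abEH_core", "dehalogenase_like"):
            seq = db[c.id].sequence
            if config.strip_nterm and c.family == "abEH_Nterm":
                seq = _strip_nterm(seq, profiles["EH-N"])
            ab_members[c.id] = seq
    for r in refs.by_family("abEH", "dehalogenase"):
        seq = r.sequence
        if config.strip_nterm and r.nterm:
            seq = _strip_nterm(seq, profiles["EH-N"])
        ab_members[r.id] = seq
    ref_groups = {r.id: r.group for r in refs}
    _family_tree("abEH", ab_members, ref_groups, config, outdir,
                 config.seed + 1, summary)
    _family_tree("LEH", leh_members, ref_groups, config, outdir,
                 config.seed + 2, summary)

    if config.chromatograms is not None:
        if config.chromatograms == "synthetic":
            df, chrom_manifest = sd.make_chromatogram_table(
                DEMO_SAMPLES, *DEMO_LINE, sigma=0.0, seed=config.seed + 3,
                s0=config.s0)
            configs = dict(DEMO_CONFIGS)
            df.to_csv(outdir / "chromatograms.csv", index=False)
        else:
            import pandas as pd
            df = pd.read_csv(config.chromatograms)
            configs = dict(config.substrate_configs)
        results = bt.reduce_table(df, s0=config.s0, substrate_configs=configs)
        bt.results_tsv(results, outdir / "biotransform.tsv")
        summary["n_biotransformations"] = len(results)
        summary["sd_flags"] = sum(r.sd_flag for r in results)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline done: %s", summary)
    return summary
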
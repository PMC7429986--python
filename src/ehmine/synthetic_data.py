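"""Ground-truthed synthetic inputs for every pipeline stage.

Real discovery campaigns start from assembled genomes that are not
bundled here, so this module manufactures the same *kinds* of input with
a machine-checkable truth manifest:

* proteomes containing planted limonene epoxide hydrolases (LEHs),
  alpha/beta-fold EHs with and without the EH-N N-terminal domain,
  fluoroacetate-dehalogenase-like decoys (DRXXRXXXR-bearing) and random
  background proteins, plus a PROKKA-style annotation table;
* additive distance matrices with a known generating tree, the regime
  where neighbor joining is exact;
* chromatogram integral tables produced from known concentrations
  through a known linear response with additive Gaussian noise.

Each enzyme family descends from a fixed per-family consensus sequence
(derived once from a hard-coded seed), so independently generated members
of a family are recognisably homologous while planted catalytic and motif
sites stay at known coordinates: scaffolds diverge by substitutions only,
never indels, which keeps every manifest claim checkable by direct string
inspection.  Background proteins are residue-i.i.d. draws -- realism is
not the objective, unambiguous truth is.

All positions in manifests are 1-based, matching how the field reports
catalytic residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ehmine.sequence_io import GeneProduct, GeneDatabase, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_SEED = 1982

FAMILIES = ("LEH", "abEH_Nterm", "abEH_core", "dehalogenase_like", "background")

# Catalytic / motif coordinates planted into every alpha/beta-fold core
# (1-based).  The acid sits at one of two alternative positions, mirroring
# the two charge-relay placements seen across the family.
AB_CORE_LEN = 300
AB_SITES = {
    "hgxp": 40,          # H-G-X-P spans 40..43, X at 42
    "nucleophile": 107,  # catalytic Asp; residue 108 is the post-Asp position
    "tyrosine": 155,
    "acid_B": 200,
    "acid_A": 235,
    "base": 275,
}
DEHALO_ARG_POSITIONS = (108, 111, 115)  # D107-R-x-x-R-x-x-x-R

# LEH coordinates follow the ReLEH numbering convention: Arg99-Asp101-Asp132
# triad, water-positioning Tyr53/Asn55, selectivity sites 80/114/116
# (wild type Ile80, Leu114, Ile116).
LEH_LEN = 149
LEH_SITES = {
    "water1": 53,
    "water2": 55,
    "sel_80": 80,
    "arg": 99,
    "asp1": 101,
    "sel_114": 114,
    "sel_116": 116,
    "asp2": 132,
}
LEH_WILDTYPE = {"water1": "Y", "water2": "N", "sel_80": "I", "sel_114": "L",
                "sel_116": "I", "arg": "R", "asp1": "D", "asp2": "D"}

EHN_LEN = 120          # EH-N domain block prepended to group-5 type cores
EHN_LINKER = "GSSG"

# Per-family within-family divergence applied by make_scaffold at
# unprotected sites; keeps independently drawn members ~85-92% identical.
SCAFFOLD_DIVERGENCE = 0.08

_BACKGROUND_ANNOTATIONS = (
    "hypothetical protein",
    "ABC transporter ATP-binding protein",
    "haloalkane dehalogenase",
    "DNA polymerase III subunit delta",
    "MFS transporter",
    "two-component sensor histidine kinase",
    "50S ribosomal protein L3",
    "acyl-CoA dehydrogenase",
)

_EH_ANNOTATIONS = {
    "LEH": "limonene-1,2-epoxide hydrolase",
    "abEH_Nterm": "epoxide hydrolase",
    "abEH_core": "epoxide hydrolase family protein",
    "dehalogenase_like": "putative epoxide hydrolase, alpha/beta fold",
}
NOISE_ANNOTATION = "hypothetical protein"


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [AA20[i] for i in rng.integers(0, 20, size=length)]


def _plant(seq: list[str], sites: dict[int, str]) -> None:
    for pos, res in sites.items():
        seq[pos - 1] = res


def _ab_core_sites(x_residue: str, post_asp: str, dehalo: bool) -> dict[int, str]:
    sites = {
        AB_SITES["hgxp"]: "H",
        AB_SITES["hgxp"] + 1: "G",
        AB_SITES["hgxp"] + 2: x_residue,
        AB_SITES["hgxp"] + 3: "P",
        AB_SITES["nucleophile"]: "D",
        AB_SITES["nucleophile"] + 1: post_asp,
        AB_SITES["tyrosine"]: "Y",
        AB_SITES["acid_A"]: "D",
        AB_SITES["acid_B"]: "E",
        AB_SITES["base"]: "H",
    }
    if dehalo:
        for p in DEHALO_ARG_POSITIONS:
            sites[p] = "R"
    return sites


def _consensus(kind: str) -> str:
    """Fixed family consensus sequences (deterministic, cached)."""
    if kind in _CONSENSUS_CACHE:
        return _CONSENSUS_CACHE[kind]
    if kind == "EHN":
        seq = _random_seq(np.random.default_rng(303), EHN_LEN)
    elif kind == "LEH_A":
        seq = _random_seq(np.random.default_rng(101), LEH_LEN)
        _plant(seq, {p: LEH_WILDTYPE[r] for r, p in LEH_SITES.items()})
    elif kind == "LEH_B":
        # a second, distant LEH lineage (MtLEH-like): 30% diverged from
        # lineage A outside the conserved sites
        rng = np.random.default_rng(606)
        seq = list(_consensus("LEH_A"))
        protected = set(LEH_SITES.values())
        _mutate(seq, 0.30, protected, rng)
    elif kind == "AB_G5":
        seq = _random_seq(np.random.default_rng(404), AB_CORE_LEN)
        _plant(seq, _ab_core_sites("W", "F", dehalo=False))
    elif kind == "AB_G8":
        seq = _random_seq(np.random.default_rng(202), AB_CORE_LEN)
        _plant(seq, _ab_core_sites("F", "W", dehalo=False))
    elif kind == "DEHALO":
        # fluoroacetate-dehalogenase-like: high identity to the group-8
        # core but hydrophilic X in H-G-X-P and the triple-arginine motif
        rng = np.random.default_rng(505)
        seq = list(_consensus("AB_G8"))
        sites = _ab_core_sites("N", "R", dehalo=True)
        _mutate(seq, 0.25, set(sites), rng)
        _plant(seq, sites)
    else:
        raise ValueError(f"unknown consensus kind {kind!r}")
    _CONSENSUS_CACHE[kind] = "".join(seq)
    return _CONSENSUS_CACHE[kind]


_CONSENSUS_CACHE: dict[str, str] = {}


def _mutate(seq: list[str], rate: float, protected: set[int], rng: np.random.Generator) -> None:
    """In-place random substitutions at `rate` per site; `protected` is 1-based."""
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if (i + 1) in protected:
            continue
        alternatives = [c for c in AA20 if c != seq[i]]
        seq[i] = alternatives[rng.integers(0, 19)]


@dataclass
class ProteomeSpec:
    """Composition and noise model of a synthetic proteome.

    ``counts`` gives the number of planted products per class; mutation is
    an additional per-site substitution rate applied on top of the
    within-family scaffold divergence.  ``annotation_noise`` is the
    fraction of planted enzymes whose annotation is replaced by an
    uninformative one (so only the domain-scan route can find them).
    """

    counts: dict[str, int] = field(default_factory=lambda: {
        "LEH": 10, "abEH_Nterm": 20, "abEH_core": 20,
        "dehalogenase_like": 10, "background": 440,
    })
    background_length_mean: float = 320.0
    background_length_sd: float = 80.0
    mutation_rate: float = 0.0
    protect_catalytic_sites: bool = True
    annotation_noise: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if cls not in FAMILIES:
                raise ValueError(f"unknown class {cls!r}")
            if n < 0:
                raise ValueError("counts must be >= 0")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if not 0 <= self.annotation_noise <= 1:
            raise ValueError("annotation_noise must be in [0, 1]")


def make_scaffold(family: str, seed: int) -> tuple[str, dict]:
    """Generate one family member and its truth-manifest entry.

    Deterministic per ``(family, seed)``.  The entry records the planted
    catalytic positions, motifs, domain span, phylogenetic group label and
    the protected (catalytic/motif) sites, all 1-based.
    """
    rng = np.random.default_rng(seed)
    if family == "LEH":
        seq = list(_consensus("LEH_A"))
        protected = set(LEH_SITES.values())
        _mutate(seq, SCAFFOLD_DIVERGENCE, protected, rng)
        entry = {
            "class": family,
            "group": "lehA",
            "positions": dict(LEH_SITES),
            "domain": {"name": "LEH", "start": 1, "end": LEH_LEN},
            "protected_sites": sorted(protected),
        }
    elif family in ("abEH_Nterm", "abEH_core", "dehalogenase_like"):
        kind = {"abEH_Nterm": "AB_G5", "abEH_core": "AB_G8",
                "dehalogenase_like": "DEHALO"}[family]
        core = list(_consensus(kind))
        x_res = core[AB_SITES["hgxp"] + 1]   # X of H-G-X-P (planted)
        variant = "A" if rng.random() < 0.5 else "B"
        core_sites = {
            "hgxp": AB_SITES["hgxp"],
            "nucleophile": AB_SITES["nucleophile"],
            "tyrosine": AB_SITES["tyrosine"],
            "base": AB_SITES["base"],
            "acid_A": AB_SITES["acid_A"],
            "acid_B": AB_SITES["acid_B"],
        }
        protected = {
            AB_SITES["hgxp"], AB_SITES["hgxp"] + 1, AB_SITES["hgxp"] + 2,
            AB_SITES["hgxp"] + 3, AB_SITES["nucleophile"],
            AB_SITES["nucleophile"] + 1, AB_SITES["tyrosine"], AB_SITES["base"],
            AB_SITES["acid_A"], AB_SITES["acid_B"],
        }
        if family == "dehalogenase_like":
            protected |= set(DEHALO_ARG_POSITIONS)
        else:
            # the per-seed acid variant: ablate the unused alternative
            unused = "acid_B" if variant == "A" else "acid_A"
            core[AB_SITES[unused] - 1] = "A"
        _mutate(core, SCAFFOLD_DIVERGENCE, protected, rng)
        offset = 0
        domain = None
        if family == "abEH_Nterm":
            ehn = list(_consensus("EHN"))
            _mutate(ehn, SCAFFOLD_DIVERGENCE, set(), rng)
            offset = EHN_LEN + len(EHN_LINKER)
            seq = ehn + list(EHN_LINKER) + core
            domain = {"name": "EH-N", "start": 1, "end": EHN_LEN}
        else:
            seq = core
        positions = {role: pos + offset for role, pos in core_sites.items()}
        entry = {
            "class": family,
            "group": {"abEH_Nterm": "group5", "abEH_core": "group8",
                      "dehalogenase_like": "group6"}[family],
            "positions": positions,
            "acid_variant": variant if family != "dehalogenase_like" else "A",
            "hgxp_x": x_res,
            "drxxrxxxr": family == "dehalogenase_like",
            "domain": domain,
            "protected_sites": sorted(p + offset for p in protected),
        }
    elif family == "background":
        raise ValueError("background proteins are drawn by make_proteome, not make_scaffold")
    else:
        raise ValueError(f"unknown family {family!r}")
    entry["length"] = len(seq)
    return "".join(seq), entry


def make_proteome(spec: ProteomeSpec, outdir: str | Path | None = None
                  ) -> tuple[GeneDatabase, dict]:
    """Generate a proteome and its truth manifest.

    Returns an in-memory `GeneDatabase` (annotations attached) and the
    manifest; when ``outdir`` is given also writes ``proteome.faa``,
    ``annotations.tsv`` and ``manifest.json`` there.
    """
    rng = np.random.default_rng(spec.seed)
    organism = f"synthetic_{spec.seed}"
    classes: list[str] = []
    for cls in FAMILIES:
        classes.extend([cls] * spec.counts.get(cls, 0))
    order = rng.permutation(len(classes))
    products: list[GeneProduct] = []
    manifest: dict = {"spec": asdict(spec), "products": {}}
    for serial, idx in enumerate(order, start=1):
        cls = classes[idx]
        gene_id = f"g{serial:05d}"
        if cls == "background":
            length = max(60, int(rng.normal(spec.background_length_mean,
                                            spec.background_length_sd)))
            seq = "".join(_random_seq(rng, length))
            annotation = _BACKGROUND_ANNOTATIONS[rng.integers(0, len(_BACKGROUND_ANNOTATIONS))]
            entry = {"class": cls, "length": length}
        else:
            scaffold_seed = int(rng.integers(0, 2**31 - 1))
            seq, entry = make_scaffold(cls, scaffold_seed)
            if spec.mutation_rate > 0:
                # only catalytic/motif sites are protected; domain spans
                # stay mutable and must survive the scan on their own
                protected = set(entry["protected_sites"]) if spec.protect_catalytic_sites else set()
                mutable = list(seq)
                _mutate(mutable, spec.mutation_rate, protected, rng)
                seq = "".join(mutable)
            annotation = _EH_ANNOTATIONS[cls]
            if spec.annotation_noise > 0 and rng.random() < spec.annotation_noise:
                annotation = NOISE_ANNOTATION
                entry["annotation_suppressed"] = True
        entry["annotation"] = annotation
        manifest["products"][gene_id] = entry
        products.append(GeneProduct(gene_id, seq, annotation, organism))
    db = GeneDatabase(products=products, sources=[(organism, "<synthetic>")])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(db.products, outdir / "proteome.faa")
        with open(outdir / "annotations.tsv", "w") as fh:
            for p in db.products:
                fh.write(f"{p.id}\t{p.annotation}\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return db, manifest


def planted_ids(manifest: dict, *classes: str) -> set[str]:
    """Ids of manifest products belonging to the given classes."""
    return {gid for gid, e in manifest["products"].items() if e["class"] in classes}


# ---------------------------------------------------------------------------
# additive distance fixtures


@dataclass
class DistanceFixture:
    ids: list[str]
    matrix: np.ndarray
    newick: str
    bipartitions: set[frozenset]
    edges: list[tuple[int, int, float]]


def make_distance_fixture(n_taxa: int, seed: int,
                          length_range: tuple[float, float] = (0.05, 1.0)
                          ) -> DistanceFixture:
    """Random unrooted binary tree and its exact path-length distances.

    Built by sequential random edge insertion; branch lengths are drawn
    uniformly from ``length_range``, so the matrix is additive by
    construction and neighbor joining must recover the topology.
    """
    if not 4 <= n_taxa <= 8:
        raise ValueError("n_taxa must be in 4..8")
    rng = np.random.default_rng(seed)
    ids = [chr(ord("A") + i) for i in range(n_taxa)]
    # nodes 0..n_taxa-1 are leaves; internal nodes appended after,
    # starting from the 3-leaf star around internal node `n_taxa`
    edges = [(0, n_taxa), (1, n_taxa), (2, n_taxa)]
    next_node = n_taxa + 1
    for leaf in range(3, n_taxa):
        k = rng.integers(0, len(edges))
        u, v = edges.pop(int(k))
        w = next_node
        next_node += 1
        edges.extend([(u, w), (w, v), (leaf, w)])
    lengths = rng.uniform(*length_range, size=len(edges))
    weighted = [(u, v, float(l)) for (u, v), l in zip(edges, lengths)]
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, l in weighted:
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))
    # leaf-to-leaf path lengths by DFS from each leaf
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, l in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + l
                    stack.append(nb)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]
    D = (D + D.T) / 2.0  # exact symmetry despite float summation order
    bipartitions = set()
    for u, v, _ in weighted:
        if u < n_taxa or v < n_taxa:
            continue  # pendant edge -> trivial split
        side = _leaves_on_side(adj, u, v, n_taxa)
        names = frozenset(ids[i] for i in side)
        bipartitions.add(_canonical_split(names, set(ids)))
    newick = _fixture_newick(adj, ids, n_taxa)
    return DistanceFixture(ids, D, newick, bipartitions, weighted)


def _canonical_split(side: frozenset, all_names: set) -> frozenset:
    """Canonical form of a bipartition: the side not containing the
    lexicographically smallest taxon."""
    anchor = min(all_names)
    return frozenset(all_names - side) if anchor in side else side


def _leaves_on_side(adj, u, v, n_taxa) -> set[int]:
    """Leaves reachable from `u` when edge (u, v) is removed."""
    seen = {u, v}
    stack = [u]
    leaves = set()
    while stack:
        node = stack.pop()
        if node < n_taxa:
            leaves.add(node)
        for nb, _ in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return leaves


def _fixture_newick(adj, ids, n_taxa) -> str:
    root = n_taxa  # first internal node; has 3 neighbours

    def render(node: int, parent: int, length: float | None) -> str:
        children = [(nb, l) for nb, l in adj[node] if nb != parent]
        if node < n_taxa:
            label = ids[node]
        else:
            label = ""
        if children:
            inner = ",".join(render(nb, node, l) for nb, l in children)
            label = f"({inner}){label}"
        return label if length is None else f"{label}:{length:.6g}"

    return render(root, -1, None) + ";"


# ---------------------------------------------------------------------------
# chromatogram tables


@dataclass
class SampleSpec:
    """True state of one enzyme x substrate biotransformation."""

    enzyme: str
    substrate: str
    enantiomer_concs: dict[str, float]  # configuration label -> mM of product
    background: float = 0.0             # mM product in the no-enzyme control
    n_replicates: int = 3


def make_chromatogram_table(samples: list[SampleSpec], slope: float,
                            intercept: float, sigma: float, seed: int,
                            standards: tuple[float, ...] = (1.0, 2.5, 5.0, 7.5, 10.0),
                            s0: float = 10.0):
    """Emit integral-table rows and a truth manifest.

    Integrals follow ``slope * conc + intercept + N(0, sigma)``.  The table
    contains the external-standard calibration series, no-enzyme control
    rows and per-replicate sample rows (one peak per enantiomer), i.e. the
    exact CSV layout `ehmine.biotransform.reduce_table` consumes.
    """
    import pandas as pd

    if slope == 0:
        raise ValueError("slope must be nonzero")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []

    def integral(conc: float) -> float:
        return slope * conc + intercept + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)

    for conc in standards:
        rows.append({"enzyme": "standard", "substrate": "standard", "replicate": 1,
                     "peak": "product", "integral": integral(conc),
                     "role": f"standard:{conc}"})
    manifest = {"slope": slope, "intercept": intercept, "sigma": sigma,
                "s0": s0, "standards": list(standards), "samples": {}}
    for s in samples:
        for rep in range(1, s.n_replicates + 1):
            rows.append({"enzyme": s.enzyme, "substrate": s.substrate,
                         "replicate": rep, "peak": "product",
                         "integral": integral(s.background), "role": "control"})
            for config, conc in s.enantiomer_concs.items():
                rows.append({"enzyme": s.enzyme, "substrate": s.substrate,
                             "replicate": rep, "peak": config,
                             "integral": integral(conc), "role": "sample"})
        total = sum(s.enantiomer_concs.values())
        corrected = max(total - s.background, 0.0)
        concs = sorted(s.enantiomer_concs.items(), key=lambda kv: -kv[1])
        if total > 0:
            ee = 100.0 * abs(concs[0][1] - (concs[1][1] if len(concs) > 1 else 0.0)) / total \
                if len(concs) <= 2 else None
            major = concs[0][0] if len(concs) < 2 or concs[0][1] != concs[1][1] else "racemic"
        else:
            ee, major = None, None
        manifest["samples"][f"{s.enzyme}|{s.substrate}"] = {
            "true_total": total, "background": s.background,
            "true_conversion": min(100.0 * corrected / s0, 100.0),
            "true_ee": ee, "major": major,
        }
    return pd.DataFrame(rows), manifest
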
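"""Candidate triage: annotation text mining and domain-profile scanning.

A gene database is queried for epoxide hydrolases by two independent
routes, mirroring how such campaigns are actually run:

1. case-insensitive substring search of the annotation text (default
   keyword: ``"epoxide hydrolase"``);
2. an ungapped position-specific scoring matrix (PSSM) scan for the two
   diagnostic domain families -- the EH N-terminal domain (Pfam accession
   PF06441, kept as a provenance label) and the limonene epoxide
   hydrolase domain (PF07858).

Profiles are built from bundled seed alignments rather than downloaded
HMMs; each profile's hit threshold is calibrated once as the 99th
percentile of best-window scores over 1000 length-preserving shuffles of
its own seed sequences (fixed seed), so a hit means "better than ~99% of
composition-matched noise".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ehmine.sequence_io import GeneDatabase
from ehmine.alignment import ALPHABET, _INDEX

logger = logging.getLogger(__name__)

DEFAULT_KEYWORDS = ["epoxide hydrolase"]
SHUFFLE_SEED = 1982
N_SHUFFLES = 1000
THRESHOLD_PERCENTILE = 99.0
PSEUDOCOUNT = 0.5
# flat background over the 20 canonical residues; matches the composition
# the synthetic proteomes are drawn from
BACKGROUND = 0.05


@dataclass
class DomainProfile:
    """Ungapped log-odds profile over the 20 residues (plus neutral X)."""

    name: str                 # "EH-N" or "LEH"
    accession: str            # Pfam accession, provenance only
    scores: np.ndarray        # (length, 21); X column all zero
    threshold: float

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class DomainHit:
    profile: str
    start: int   # 1-based, inclusive
    end: int     # 1-based, inclusive
    score: float


@dataclass
class CandidateEH:
    """A gene product with the evidence gathered about it.

    Mining sets the evidence flags; classification later fills motif
    hits, triad assignments and the family label.
    """

    id: str
    annotation_hit: bool = False
    domain_hits: dict[str, DomainHit] = field(default_factory=dict)
    motif_hits: list = field(default_factory=list)
    triads: dict = field(default_factory=dict)
    n_terminal_domain: bool = False
    family: str | None = None
    best_reference: str | None = None
    best_identity: float | None = None
    selectivity: object | None = None


def textmine(db: GeneDatabase, keywords: list[str] | None = None) -> set[str]:
    """Ids whose annotation contains any keyword (case-insensitive).

    Monotone in the keyword set: adding keywords can only add hits.
    """
    if keywords is None:
        keywords = DEFAULT_KEYWORDS
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    return {
        p.id for p in db
        if any(k in p.annotation.lower() for k in lowered)
    }


def _profile_matrix(rows: list[str], background: float = BACKGROUND) -> np.ndarray:
    """Log-odds matrix from aligned seed rows; >50%-gap columns dropped."""
    n_rows = len(rows)
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("seed alignment rows differ in length")
    cols = []
    for j in range(width):
        column = [r[j] for r in rows]
        if column.count("-") * 2 > n_rows:
            continue
        counts = np.zeros(20)
        for ch in column:
            if ch in ("-", "X"):
                continue
            counts[_INDEX[ch]] += 1
        total = counts.sum() + 20 * PSEUDOCOUNT
        probs = (counts + PSEUDOCOUNT) / total
        scores = np.log2(probs / background)
        cols.append(np.append(scores, 0.0))  # X scores 0
    return np.array(cols)


def best_window_score(seq: str, scores: np.ndarray) -> tuple[float, int] | None:
    """Best ungapped placement of the profile along `seq`.

    Returns ``(score, start)`` with a 1-based start, or None when the
    sequence is shorter than the profile.  Ties take the leftmost start.
    """
    L = scores.shape[0]
    n = len(seq)
    if n < L:
        return None
    idx = np.array([_INDEX[c] for c in seq], dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    per_window = scores[np.arange(L), windows].sum(axis=1)
    best = int(np.argmax(per_window))
    return float(per_window[best]), best + 1


def build_domain_profile(seed_rows: list[str], name: str, accession: str,
                         background: float = BACKGROUND,
                         shuffle_seed: int = SHUFFLE_SEED) -> DomainProfile:
    """Build a PSSM from a seed alignment and calibrate its threshold.

    The threshold is the 99th percentile of best-window scores over 1000
    length-preserving shuffles of the (degapped) seed sequences, drawn
    reproducibly from ``shuffle_seed``.
    """
    if len(seed_rows) < 3:
        raise ValueError("need at least 3 aligned seed sequences")
    if not 0 < background < 1:
        raise ValueError("background frequency must be in (0, 1)")
    scores = _profile_matrix(seed_rows, background)
    if scores.shape[0] < 10:
        raise ValueError("profile too short after gap-column removal")
    rng = np.random.default_rng(shuffle_seed)
    # Decoys are length-preserving shuffles of the pooled (degapped) seed
    # residues.  Pooling makes each decoy several profile-lengths long, so
    # the null is a max-over-windows statistic like a real scan, not a
    # single-window draw; this keeps the false-hit rate near the nominal
    # 1% for full-length query proteins.
    pool = np.array(list("".join(r.replace("-", "") for r in seed_rows)))
    null_scores = []
    for _ in range(N_SHUFFLES):
        shuffled = "".join(pool[rng.permutation(len(pool))])
        hit = best_window_score(shuffled, scores)
        if hit is not None:
            null_scores.append(hit[0])
    threshold = float(np.percentile(null_scores, THRESHOLD_PERCENTILE))
    return DomainProfile(name=name, accession=accession, scores=scores,
                         threshold=threshold)


def scan_domain(seq: str, profile: DomainProfile) -> DomainHit | None:
    """Best ungapped window; a hit iff its score reaches the threshold."""
    found = best_window_score(seq, profile.scores)
    if found is None:
        logger.warning("sequence shorter than %s profile (%d < %d); no scan",
                       profile.name, len(seq), profile.length)
        return None
    score, start = found
    if score < profile.threshold:
        return None
    return DomainHit(profile=profile.name, start=start,
                     end=start + profile.length - 1, score=score)


def scan_database(db: GeneDatabase, profiles: list[DomainProfile]) -> dict[str, dict[str, DomainHit]]:
    """Scan every product against every profile; only hits are returned."""
    hits: dict[str, dict[str, DomainHit]] = {}
    for p in db:
        for profile in profiles:
            hit = scan_domain(p.sequence, profile)
            if hit is not None:
                hits.setdefault(p.id, {})[profile.name] = hit
    return hits


def merge_candidates(text_hits: set[str],
                     domain_hits: dict[str, dict[str, DomainHit]],
                     db: GeneDatabase) -> list[CandidateEH]:
    """Union of the two evidence routes, in database order."""
    for gene_id in set(text_hits) | set(domain_hits):
        if gene_id not in db:
            raise KeyError(f"unknown gene id {gene_id!r}")
    out = []
    for p in db:
        if p.id in text_hits or p.id in domain_hits:
            out.append(CandidateEH(
                id=p.id,
                annotation_hit=p.id in text_hits,
                domain_hits=dict(domain_hits.get(p.id, {})),
            ))
    return out


def candidates_tsv(candidates: list[CandidateEH], db: GeneDatabase, path) -> None:
    """Report candidates as TSV (id, organism, evidence, scores)."""
    with open(path, "w") as fh:
        fh.write("id\torganism\tannotation_hit\tdomain_hits\tscores\n")
        for c in candidates:
            product = db[c.id]
            names = ",".join(sorted(c.domain_hits)) or "-"
            scores = ",".join(f"{c.domain_hits[n].score:.2f}" for n in sorted(c.domain_hits)) or "-"
            fh.write(f"{c.id}\t{product.organism}\t{int(c.annotation_hit)}\t{names}\t{scores}\n")
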
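"""Regenerate the bundled synthetic seed alignments and reference set."""
import numpy as np
from pathlib import Path

from ehmine import synthetic_data as sd

DATA = Path(__file__).resolve().parents[1] / "src" / "ehmine" / "data"
DATA.mkdir(parents=True, exist_ok=True)


def mutated_copy(consensus: str, rate: float, protected: set[int], seed: int) -> str:
    rng = np.random.default_rng(seed)
    seq = list(consensus)
    sd._mutate(seq, rate, protected, rng)
    return "".join(seq)


def write_afa(path, rows):
    with open(path, "w") as fh:
        for i, row in enumerate(rows, 1):
            fh.write(f">seed{i}\n{row}\n")


# --- seed alignments (gap-free by construction: substitutions only) -------
ehn = sd._consensus("EHN")
write_afa(DATA / "ehn_seed.afa",
          [mutated_copy(ehn, 0.08, set(), 7000 + i) for i in range(5)])

leh_a = sd._consensus("LEH_A")
leh_b = sd._consensus("LEH_B")
prot = set(sd.LEH_SITES.values())
rows = [mutated_copy(leh_a, 0.08, prot, 7100 + i) for i in range(4)]
rows += [mutated_copy(leh_b, 0.08, prot, 7200 + i) for i in range(2)]
write_afa(DATA / "leh_seed.afa", rows)

# --- reference set ---------------------------------------------------------
refs = []


def add_ab(ref_id, family_key, group, seed, nterm):
    seq, entry = sd.make_scaffold(family_key, seed)
    seq = list(seq)
    pos = entry["positions"]
    if family_key != "dehalogenase_like":
        # references carry an acid at BOTH charge-relay anchors so they can
        # anchor candidates of either variant
        seq[pos["acid_A"] - 1] = "D"
        seq[pos["acid_B"] - 1] = "E"
    family = "dehalogenase" if family_key == "dehalogenase_like" else "abEH"
    roles = {r: pos[r] for r in ("nucleophile", "base", "tyrosine", "acid_A", "acid_B")}
    refs.append({
        "id": ref_id, "family": family, "group": group, "nterm": nterm,
        "positions": roles, "sequence": "".join(seq),
    })


def add_leh(ref_id, group, seed, releh_like, lineage="LEH_A"):
    if lineage == "LEH_A":
        seq, entry = sd.make_scaffold("LEH", seed)
        pos = entry["positions"]
    else:
        seq = mutated_copy(sd._consensus("LEH_B"), 0.08, set(sd.LEH_SITES.values()), seed)
        pos = dict(sd.LEH_SITES)
    roles = {r: pos[r] for r in ("asp1", "arg", "asp2", "water1", "water2")}
    if releh_like:
        roles.update({r: pos[r] for r in ("sel_80", "sel_114", "sel_116")})
    refs.append({
        "id": ref_id, "family": "LEH", "group": group,
        "releh_like": releh_like, "positions": roles, "sequence": seq,
    })


add_ab("refG5a", "abEH_Nterm", "group5", 9001, True)
add_ab("refG5b", "abEH_Nterm", "group5", 9002, True)
add_ab("refG8a", "abEH_core", "group8", 9003, False)
add_ab("refG8b", "abEH_core", "group8", 9004, False)
add_ab("refG6dh", "dehalogenase_like", "group6", 9005, False)
add_leh("refLEHa1", "lehA", 9101, releh_like=True)
add_leh("refLEHa2", "lehA", 9102, releh_like=False)
add_leh("refLEHb1", "lehB", 9103, releh_like=False, lineage="LEH_B")
add_leh("refLEHb2", "lehB", 9104, releh_like=False, lineage="LEH_B")

with open(DATA / "references.fasta", "w") as fh:
    for r in refs:
        fh.write(f">{r['id']} synthetic {r['family']} reference scaffold\n{r['sequence']}\n")

import yaml
meta = {"references": [
    {k: v for k, v in r.items() if k != "sequence"} for r in refs
]}
with open(DATA / "references.yaml", "w") as fh:
    fh.write("# Synthetic reference scaffolds with annotated catalytic positions.\n"
             "# Substitute real enzyme sequences (AnEH/StEH/AgAD1/ReLEH...) via\n"
             "# ReferenceSet.from_files with the same schema.\n")
    yaml.safe_dump(meta, fh, sort_keys=False)

print("wrote", sorted(p.name for p in DATA.iterdir()))
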
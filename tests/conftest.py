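"""Shared fixtures: hand-built alignments and seeded synthetic libraries."""

import numpy as np
import pytest

from tagbarcode.seqio import BarcodeAlignment, BarcodeRecord
from tagbarcode.synth import SynthConfig, generate


def make_alignment(entries, marker="mt-test", genus_of=None, tribe=""):
    """Build a BarcodeAlignment from (seq_id, species, residues) triples.

    ``genus_of`` maps species -> genus; default derives the genus from the
    species name's first token.
    """
    records = []
    for seq_id, species, residues in entries:
        genus = (genus_of or {}).get(species, species.split("_")[0])
        records.append(
            BarcodeRecord(
                seq_id=seq_id,
                species=species,
                genus=genus,
                tribe=tribe,
                marker=marker,
                residues=residues,
            )
        )
    return BarcodeAlignment(marker=marker, records=records)


def mutate_at(base: str, changes: dict[int, str]) -> str:
    """Return ``base`` with 1-based positions replaced per ``changes``."""
    out = list(base)
    for pos, ch in changes.items():
        out[pos - 1] = ch
    return "".join(out)


@pytest.fixture(scope="session")
def well_separated():
    """10 species x 10 individuals, intra 0.01 / inter 0.10, no hypervariable
    columns: the parameter-recovery reference library."""
    cfg = SynthConfig(
        n_genera=1,
        species_per_genus=10,
        individuals_per_species=10,
        length=658,
        target_intra=0.01,
        target_inter=0.10,
        seed=1,
    )
    aln, ledger = generate(cfg)
    return aln, ledger


@pytest.fixture(scope="session")
def overlap_fixture():
    """Deterministic two-species alignment engineered to flip overlap -> gap.

    Species A (6 individuals, length 100) carries four hypervariable columns
    (positions 10, 30, 50, 70) split 3 modal / 3 alternate, with individuals
    4-6 carrying every alternate state, so one intra pair differs at all 4
    columns (max intra = 4 diffs).  Species B is 6 identical sequences
    differing from A's modal sequence at 3 fixed columns (min inter = 3
    diffs).  Hence overlap before tagging; after removing A's tag both
    intraspecific distributions collapse to 0 and a gap appears.
    """
    rng = np.random.default_rng(42)
    base = "".join(rng.choice(list("ACGT"), p=[0.36, 0.13, 0.10, 0.41], size=100))
    base = mutate_at(base, {10: "A", 30: "C", 50: "G", 70: "T"})
    hv_alt = {10: "G", 30: "T", 50: "A", 70: "C"}  # transitions at the hv columns
    b_seq = mutate_at(base, {5: "G" if base[4] == "A" else "A",
                             45: "C" if base[44] == "T" else "T",
                             85: "G" if base[84] == "A" else "A"})
    entries = []
    for k in range(1, 4):
        entries.append((f"A_i{k}", "SpA", base))
    for k in range(4, 7):
        entries.append((f"A_i{k}", "SpA", mutate_at(base, hv_alt)))
    for k in range(1, 7):
        entries.append((f"B_i{k}", "SpB", b_seq))
    genus_of = {"SpA": "GenX", "SpB": "GenX"}
    return make_alignment(entries, genus_of=genus_of)
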
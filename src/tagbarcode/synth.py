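"""Synthetic barcode-library generator with controlled divergence structure.

Emulates a multi-species mitochondrial barcode library: AT-rich base
composition, low intraspecific and roughly ten-fold higher interspecific
K2P divergence, and -- optionally -- injected within-species hypervariable
columns that create intra/inter overlap, the failure mode the tag-barcode
method targets.

The model is deliberately simple: each genus has an ancestral sequence
drawn i.i.d. from the stationary base frequencies; each species ancestor
mutates from its genus ancestor at rate ``target_inter / 2`` per site
(star phylogeny within the genus), and each individual mutates from its
species ancestor at rate ``target_intra / 2``, so the expected pairwise
divergence between conspecific individuals is ~``target_intra`` and
between congeneric species ~``target_inter``.  Substitutions split into
transitions and transversions per the transition/transversion ratio, so
the K2P estimator is correctly specified.  No indels are generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tagbarcode.divstats import inter_distances, intra_distances
from tagbarcode.distance import distance_matrix
from tagbarcode.seqio import BarcodeAlignment, BarcodeRecord

__all__ = ["SynthConfig", "generate", "realized_divergence"]

_BASES = np.array(list("ACGT"))
#: transition partner of each base (A<->G, C<->T), indexed by base code
_TRANSITION = np.array([2, 3, 0, 1])
#: the two transversion partners of each base code
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate an AT-rich insect COI library."""

    n_genera: int = 1
    species_per_genus: int = 10
    individuals_per_species: int = 10
    length: int = 658
    target_intra: float = 0.01
    target_inter: float = 0.10
    ti_tv_ratio: float = 2.0
    #: stationary frequencies of A, C, G, T (~75% A+T)
    base_freqs: tuple = (0.36, 0.13, 0.10, 0.41)
    hv_species: tuple = ()
    hv_n_columns: int = 0
    hv_variability: float = 0.5
    #: individuals for hypervariable species (None = individuals_per_species);
    #: real libraries often under-sample exactly the problematic species
    hv_individuals: int | None = None
    marker: str = "COI"
    tribe: str = "Tribe1"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        for name in ("n_genera", "species_per_genus", "individuals_per_species", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.target_intra < self.target_inter:
            raise ValueError("target_intra must be < target_inter")
        if self.hv_n_columns > self.length:
            raise ValueError("hv_n_columns exceeds alignment length")
        if not 0.0 <= self.hv_variability <= 0.75:
            # with a single modal state and 3 alternatives the non-modal
            # fraction cannot exceed 3/4 while the modal state stays modal
            raise ValueError("hv_variability must be in [0, 0.75]")


def _mutate(rng: np.random.Generator, seq: np.ndarray, branch: float, ti_tv: float) -> np.ndarray:
    """Evolve a sequence along a branch of the given expected length.

    ``branch`` is in expected substitutions per site; per-site transition
    and transversion difference probabilities follow the K2P process with
    transition rate alpha and per-target transversion rate beta, where the
    transition/transversion ratio is alpha/(2 beta).  Sites evolve i.i.d.,
    so the K2P estimator is consistent for the branch length.
    """
    if branch <= 0:
        return seq.copy()
    b = branch / (2.0 * ti_tv + 2.0)  # beta * t
    a = branch - 2.0 * b  # alpha * t
    P = 0.25 + 0.25 * np.exp(-4.0 * b) - 0.5 * np.exp(-2.0 * (a + b))
    Q = 0.5 - 0.5 * np.exp(-4.0 * b)
    u = rng.random(len(seq))
    out = seq.copy()
    ts = u < P
    tv = (u >= P) & (u < P + Q)
    out[ts] = _TRANSITION[seq[ts]]
    out[tv] = _TRANSVERSIONS[seq[tv], rng.integers(0, 2, size=int(tv.sum()))]
    return out


def _inject_hypervariable(
    rng: np.random.Generator,
    rows: np.ndarray,
    columns: np.ndarray,
    variability: float,
) -> list[dict]:
    """Overwrite the given columns so the non-modal fraction == variability."""
    n = rows.shape[0]
    k = int(round(variability * n))
    ledger = []
    for col in columns:
        modal = int(rng.integers(0, 4))
        newcol = np.full(n, modal)
        if k:
            # spread non-modal residues over the other three bases, at most
            # n - k per base so the modal state keeps (or ties) the majority
            alts = [b for b in range(4) if b != modal]
            counts = []
            left = k
            for _ in alts:
                take = min(left, (k + 2) // 3)
                counts.append(take)
                left -= take
            pos = rng.permutation(n)[:k]
            flat = []
            for b, c in zip(alts, counts):
                flat.extend([b] * c)
            newcol[pos] = flat[:k]
        rows[:, col] = newcol
        realized = 1.0 - np.bincount(newcol, minlength=4).max() / n
        ledger.append(
            {"column_1based": int(col) + 1, "modal_base": "ACGT"[modal],
             "n_non_modal": k, "realized_variability": float(realized)}
        )
    return ledger


def generate(config: SynthConfig) -> tuple[BarcodeAlignment, dict]:
    """Generate a labeled synthetic barcode alignment.

    Returns the alignment (species names ``G<g>_sp<s>``, individuals
    ``G<g>_sp<s>_i<k>``) and a ledger dict echoing the configuration and
    recording every injected hypervariable column per species.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.base_freqs, dtype=float)
    records: list[BarcodeRecord] = []
    species_rows: dict[str, list[int]] = {}
    rows: list[np.ndarray] = []

    for g in range(1, config.n_genera + 1):
        genus = f"G{g:02d}"
        genus_anc = rng.choice(4, size=config.length, p=freqs)
        for s in range(1, config.species_per_genus + 1):
            species = f"{genus}_sp{s:02d}"
            sp_anc = _mutate(
                rng, genus_anc, config.target_inter / 2.0, config.ti_tv_ratio
            )
            n_ind = (
                config.hv_individuals
                if config.hv_individuals is not None and species in config.hv_species
                else config.individuals_per_species
            )
            for k in range(1, n_ind + 1):
                seq = _mutate(
                    rng, sp_anc, config.target_intra / 2.0, config.ti_tv_ratio
                )
                species_rows.setdefault(species, []).append(len(rows))
                rows.append(seq)
                records.append(
                    (f"{species}_i{k:02d}", species, genus)
                )

    mat = np.vstack(rows)
    injected: dict[str, list[dict]] = {}
    if config.hv_n_columns and config.hv_species:
        for sp in config.hv_species:
            if sp not in species_rows:
                raise ValueError(f"hv_species {sp!r} not generated by this config")
            cols = rng.choice(config.length, size=config.hv_n_columns, replace=False)
            sub = mat[species_rows[sp]]
            injected[sp] = _inject_hypervariable(
                rng, sub, np.sort(cols), config.hv_variability
            )
            mat[species_rows[sp]] = sub

    barcode_records = [
        BarcodeRecord(
            seq_id=sid,
            species=sp,
            genus=genus,
            tribe=config.tribe,
            marker=config.marker,
            residues="".join(_BASES[mat[i]]),
        )
        for i, (sid, sp, genus) in enumerate(records)
    ]
    aln = BarcodeAlignment(marker=config.marker, records=barcode_records)
    ledger = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "injected_columns": injected,
    }
    return aln, ledger


def realized_divergence(
    aln: BarcodeAlignment, labels: dict[str, str], genera: dict[str, str] | None = None
) -> tuple[float, float]:
    """(mean intraspecific, mean congeneric interspecific) K2P divergence.

    Used to certify that a generated fixture realizes its target rates;
    computed through the distance and divergence-statistics modules.
    """
    dm = distance_matrix(aln, "k2p")
    intra = intra_distances(dm, labels)
    inter = inter_distances(dm, labels, genera)
    mean_intra = float(np.mean(intra)) if intra else float("nan")
    mean_inter = float(np.mean(inter)) if inter else float("nan")
    return mean_intra, mean_inter
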
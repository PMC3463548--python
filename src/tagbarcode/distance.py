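"""Pairwise substitution counting and K2P / TN93 / p distances.

All comparisons use pairwise deletion: an alignment column contributes to a
pair only if both residues are unambiguous DNA (A, C, G, T).  Gaps, N and
IUPAC ambiguity codes are excluded from both the site count and the
substitution counts of that pair, never fractionally counted.

Distances that fall outside the model domain (a logarithm argument <= 0,
i.e. substitutional saturation, or zero comparable sites) are *undefined*:
they are returned as NaN, flagged in :class:`DistanceMatrix.undefined_pairs`
and must be excluded from downstream averages -- never silently zeroed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tagbarcode.seqio import BarcodeAlignment, encode_residues

__all__ = [
    "SubstitutionCounts",
    "DistanceMatrix",
    "count_substitutions",
    "p_distance",
    "k2p_distance",
    "tn93_distance",
    "distance_matrix",
    "saturation_profile",
    "MODELS",
]

MODELS = ("k2p", "tn93", "p")


@dataclass(frozen=True)
class SubstitutionCounts:
    """Per-pair substitution tally over comparable (both-unambiguous) sites.

    ``s`` splits into purine transitions ``s1`` (A<->G) and pyrimidine
    transitions ``s2`` (C<->T); ``v`` counts transversions.
    """

    n_sites: int
    s: int
    v: int
    s1: int
    s2: int

    def __post_init__(self) -> None:
        assert self.s == self.s1 + self.s2
        assert 0 <= self.s + self.v <= self.n_sites


def _encode_pair(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    mat = encode_residues([a.upper(), b.upper()])
    return mat[0], mat[1]


def _counts_from_codes(x: np.ndarray, y: np.ndarray) -> SubstitutionCounts:
    ok = (x != 255) & (y != 255)
    xs, ys = x[ok], y[ok]
    diff = xs != ys
    # transition = change within a parity class (A=0,G=2 purines; C=1,T=3 pyrimidines)
    same_class = (xs % 2) == (ys % 2)
    ts = diff & same_class
    s1 = int(np.sum(ts & (xs % 2 == 0)))
    s2 = int(np.sum(ts & (xs % 2 == 1)))
    v = int(np.sum(diff & ~same_class))
    return SubstitutionCounts(n_sites=int(ok.sum()), s=s1 + s2, v=v, s1=s1, s2=s2)


def count_substitutions(a: str, b: str) -> SubstitutionCounts:
    """Count transitions/transversions between two aligned residue strings.

    Columns where either residue is a gap, N or an ambiguity code are
    deleted pairwise.  Symmetric in its arguments.
    """
    return _counts_from_codes(*_encode_pair(a, b))


def p_distance(c: SubstitutionCounts) -> float:
    """Proportion of differing comparable sites; NaN if no sites."""
    if c.n_sites == 0:
        return float("nan")
    return (c.s + c.v) / c.n_sites


def k2p_distance(c: SubstitutionCounts) -> float:
    """Kimura two-parameter distance from substitution counts.

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q) with P = s/n, Q = v/n.
    Returns NaN when no comparable sites exist or either logarithm argument
    is <= 0 (saturation).
    """
    if c.n_sites == 0:
        return float("nan")
    P, Q = c.s / c.n_sites, c.v / c.n_sites
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2)) + 0.0  # no -0.0


def _tn93_from_codes(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != 255) & (y != 255)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    c = _counts_from_codes(x, y)
    # empirical base frequencies: arithmetic mean of the two sequences,
    # over the comparable sites of this pair
    freqs = np.zeros(4)
    for seq in (x[ok], y[ok]):
        freqs += np.bincount(seq, minlength=4)[:4]
    freqs /= freqs.sum()
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = c.s1 / n, c.s2 / n, c.v / n

    d = 0.0
    # each term vanishes (count = 0) whenever its denominator does, because a
    # purine transition needs purines present, etc.; guard accordingly
    if gA * gG > 0 and gR > 0:
        w = 1.0 - gR * P1 / (2.0 * gA * gG) - Q / (2.0 * gR)
        if w <= 0:
            return float("nan")
        d += -2.0 * gA * gG / gR * np.log(w)
    elif P1 > 0:
        return float("nan")
    if gT * gC > 0 and gY > 0:
        w = 1.0 - gY * P2 / (2.0 * gT * gC) - Q / (2.0 * gY)
        if w <= 0:
            return float("nan")
        d += -2.0 * gT * gC / gY * np.log(w)
    elif P2 > 0:
        return float("nan")
    if gR * gY > 0:
        w = 1.0 - Q / (2.0 * gR * gY)
        if w <= 0:
            return float("nan")
        d += (
            -2.0
            * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
            * np.log(w)
        )
    elif Q > 0:
        return float("nan")
    return float(d)


def tn93_distance(a: str, b: str) -> float:
    """Tamura-Nei (TN93) distance between two aligned residue strings.

    Distinguishes purine (A<->G) from pyrimidine (C<->T) transitions and
    uses empirical base frequencies averaged over the pair's comparable
    sites.  Reduces to K2P when frequencies are equal and the two transition
    classes are balanced.  NaN when undefined (no sites or saturation).
    """
    return _tn93_from_codes(*_encode_pair(a, b))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair site counts.

    ``values[i, j]`` is NaN for pairs where the model distance is undefined;
    those pairs are listed in ``undefined_pairs``.
    """

    ids: list[str]
    model: str
    values: np.ndarray
    n_sites: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        """Square tab-separated matrix with an id header row/column."""
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")

    def submatrix(self, seq_ids: list[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in seq_ids]
        und = [
            (a, b)
            for a, b in self.undefined_pairs
            if a in set(seq_ids) and b in set(seq_ids)
        ]
        return DistanceMatrix(
            ids=list(seq_ids),
            model=self.model,
            values=self.values[np.ix_(idx, idx)],
            n_sites=self.n_sites[np.ix_(idx, idx)],
            undefined_pairs=und,
        )


def _pair_distance_codes(x: np.ndarray, y: np.ndarray, model: str) -> tuple[float, int]:
    if model == "tn93":
        c = _counts_from_codes(x, y)
        return _tn93_from_codes(x, y), c.n_sites
    c = _counts_from_codes(x, y)
    if model == "k2p":
        return k2p_distance(c), c.n_sites
    if model == "p":
        return p_distance(c), c.n_sites
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def distance_matrix(aln: BarcodeAlignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix for an alignment under the given model.

    Exactly symmetric with a zero diagonal.  Undefined pairs (saturated or no
    comparable sites) are NaN, collected in ``undefined_pairs`` and reported
    with a warning.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if len(aln) < 2:
        raise ValueError("distance_matrix needs at least 2 records")
    codes = aln.to_array()
    n = len(aln)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    undefined = []
    for i, j in itertools.combinations(range(n), 2):
        d, ns = _pair_distance_codes(codes[i], codes[j], model)
        values[i, j] = values[j, i] = d
        sites[i, j] = sites[j, i] = ns
        if np.isnan(d):
            undefined.append((aln.ids[i], aln.ids[j]))
    for i in range(n):
        sites[i, i] = int(np.sum(codes[i] != 255))
    if undefined:
        warnings.warn(
            f"{len(undefined)} pair(s) have undefined {model} distances; "
            "they are excluded from averages",
            stacklevel=2,
        )
    return DistanceMatrix(
        ids=list(aln.ids),
        model=model,
        values=values,
        n_sites=sites,
        undefined_pairs=undefined,
    )


def _linregress_or_nan(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, R^2); NaNs when the regression is degenerate (constant x)."""
    if len(x) < 2 or np.allclose(x, x[0]):
        return float("nan"), float("nan")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def saturation_profile(
    aln: BarcodeAlignment, by_codon_position: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transitions/transversions per pair against the TN93 distance.

    Substitution saturation is diagnosed by plotting s and v against a
    corrected distance: a linear, non-plateauing relationship indicates the
    marker is usable for distance-based identification.  Returns the
    per-pair table (columns id1, id2, position_class, tn93, s, v) and a
    linearity summary with the least-squares slope and R^2 of s-vs-distance
    and v-vs-distance per codon-position class ('all' when unflagged;
    reading frame is assumed to start at column 1).
    """
    codes = aln.to_array()
    L = aln.length
    classes: dict[str, np.ndarray] = {"all": np.arange(L)}
    if by_codon_position:
        classes = {str(p + 1): np.arange(p, L, 3) for p in range(3)}
    rows = []
    for i, j in itertools.combinations(range(len(aln)), 2):
        d = _tn93_from_codes(codes[i], codes[j])
        for cls, cols in classes.items():
            c = _counts_from_codes(codes[i][cols], codes[j][cols])
            rows.append(
                {
                    "id1": aln.ids[i],
                    "id2": aln.ids[j],
                    "position_class": cls,
                    "tn93": d,
                    "s": c.s,
                    "v": c.v,
                }
            )
    table = pd.DataFrame(rows)
    summaries = []
    for cls, grp in table.groupby("position_class", sort=True):
        ok = grp["tn93"].notna()
        x = grp.loc[ok, "tn93"].to_numpy(float)
        for kind in ("s", "v"):
            slope, r2 = _linregress_or_nan(x, grp.loc[ok, kind].to_numpy(float))
            summaries.append(
                {
                    "position_class": cls,
                    "response": kind,
                    "n_pairs": int(ok.sum()),
                    "slope": slope,
                    "r_squared": r2,
                }
            )
    return table, pd.DataFrame(summaries)
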
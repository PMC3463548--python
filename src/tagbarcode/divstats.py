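"""Divergence summary statistics, alignment site classes, and gap analysis.

Three layers of summary are provided, mirroring how barcode libraries are
usually reported:

* per-alignment base composition and conserved / variable /
  parsimony-informative site counts;
* per-species intraspecific divergence (mean pairwise distance, theta,
  coalescent depth = maximum intraspecific distance) and per-genus /
  per-tribe interspecific divergence (mean over between-species pairs,
  with both SD and SE of the pair distances);
* the barcoding-gap report: the pooled intra- and inter-specific distance
  distributions, their histograms, and the interval between the maximum
  intraspecific and minimum interspecific distance, classified as a gap
  (max intra <= min inter) or an overlap (max intra > min inter).

Undefined (NaN) distances are excluded from every average, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tagbarcode.distance import DistanceMatrix
from tagbarcode.seqio import BarcodeAlignment, UNAMBIGUOUS

__all__ = [
    "composition_and_sites",
    "species_divergence",
    "group_divergence",
    "GapReport",
    "gap_report",
    "prune_synonyms",
    "intra_distances",
    "inter_distances",
]


def composition_and_sites(aln: BarcodeAlignment) -> dict:
    """Base frequencies and conserved/variable/parsimony-informative counts.

    Frequencies are computed over unambiguous residues only.  Per column,
    counting only non-gap unambiguous residues: conserved = exactly one
    state present; variable = >= 2 states; parsimony-informative = >= 2
    states each present in >= 2 sequences.  Columns with no unambiguous
    residue are counted in ``n_sites_no_data``.
    """
    if len(aln) < 2:
        raise ValueError("composition_and_sites needs at least 2 records")
    codes = aln.to_array()
    total = np.zeros(4)
    conserved = variable = informative = no_data = 0
    for col in codes.T:
        counts = np.bincount(col[col != 255], minlength=4)[:4]
        total += counts
        states = int(np.sum(counts > 0))
        if states == 0:
            no_data += 1
        elif states == 1:
            conserved += 1
        else:
            variable += 1
            if int(np.sum(counts >= 2)) >= 2:
                informative += 1
    freqs = total / total.sum() if total.sum() else np.zeros(4)
    return {
        "base_freqs": dict(zip(UNAMBIGUOUS, freqs.tolist())),
        "n_conserved": conserved,
        "n_variable": variable,
        "n_parsimony_informative": informative,
        "n_sites_no_data": no_data,
        "length": aln.length,
    }


def _pair_values(dm: DistanceMatrix, idx_a: list[int], idx_b: list[int] | None = None):
    """Defined distances over pairs within idx_a, or between idx_a and idx_b."""
    vals = []
    if idx_b is None:
        for k, i in enumerate(idx_a):
            for j in idx_a[k + 1 :]:
                vals.append(dm.values[i, j])
    else:
        for i in idx_a:
            for j in idx_b:
                vals.append(dm.values[i, j])
    vals = np.asarray(vals, dtype=float)
    n_undef = int(np.isnan(vals).sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} undefined distance(s) excluded from a divergence summary",
            stacklevel=3,
        )
    return vals[~np.isnan(vals)]


def _species_indices(dm: DistanceMatrix, labels: dict[str, str]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i, sid in enumerate(dm.ids):
        if sid not in labels:
            raise ValueError(f"no species label for {sid!r}")
        out.setdefault(labels[sid], []).append(i)
    return {sp: out[sp] for sp in sorted(out)}


def species_divergence(dm: DistanceMatrix, labels: dict[str, str]) -> pd.DataFrame:
    """Per-species intraspecific divergence; singletons are omitted.

    Columns: species, n (sequences), n_pairs, mean_intra (mean pairwise
    distance), theta (identical to mean_intra at the species level -- the
    two diverge only when aggregating across species, see
    ``genus_intraspecific_summary``), coalescent_depth (maximum pairwise
    intraspecific distance).
    """
    rows = []
    for sp, idx in _species_indices(dm, labels).items():
        if len(idx) < 2:
            continue
        vals = _pair_values(dm, idx)
        if len(vals) == 0:
            warnings.warn(f"species {sp!r}: all intraspecific distances undefined")
            continue
        rows.append(
            {
                "species": sp,
                "n": len(idx),
                "n_pairs": len(vals),
                "mean_intra": float(vals.mean()),
                "theta": float(vals.mean()),
                "coalescent_depth": float(vals.max()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "n", "n_pairs", "mean_intra", "theta", "coalescent_depth"],
    )


def group_divergence(
    dm: DistanceMatrix, labels: dict[str, str], groups: dict[str, str]
) -> pd.DataFrame:
    """Interspecific divergence within each genus or tribe.

    ``labels`` maps seq_id -> species and ``groups`` maps seq_id -> group
    (genus or tribe).  For each group with >= 2 species, the mean is taken
    over all between-species sequence pairs within the group (within-species
    pairs excluded); the SD (ddof=1) and SE of those pair distances are both
    reported.  Groups with a single species are omitted.
    """
    by_group: dict[str, dict[str, list[int]]] = {}
    for i, sid in enumerate(dm.ids):
        if sid not in labels or sid not in groups:
            raise ValueError(f"no label for {sid!r}")
        by_group.setdefault(groups[sid], {}).setdefault(labels[sid], []).append(i)
    rows = []
    for grp in sorted(by_group):
        species = sorted(by_group[grp])
        if len(species) < 2:
            continue
        vals = []
        for k, sa in enumerate(species):
            for sb in species[k + 1 :]:
                vals.extend(_pair_values(dm, by_group[grp][sa], by_group[grp][sb]))
        vals = np.asarray(vals, dtype=float)
        if len(vals) == 0:
            continue
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "group": grp,
                "n_species": len(species),
                "n_pairs": len(vals),
                "mean_inter": float(vals.mean()),
                "sd": sd,
                "se": sd / np.sqrt(len(vals)),
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "n_species", "n_pairs", "mean_inter", "sd", "se"]
    )


def intra_distances(dm: DistanceMatrix, labels: dict[str, str]) -> list[float]:
    """Pooled defined intraspecific pair distances across all species."""
    vals: list[float] = []
    for idx in _species_indices(dm, labels).values():
        if len(idx) >= 2:
            vals.extend(_pair_values(dm, idx).tolist())
    return vals


def inter_distances(
    dm: DistanceMatrix, labels: dict[str, str], groups: dict[str, str] | None = None
) -> list[float]:
    """Pooled defined between-species pair distances.

    With ``groups`` given (seq_id -> genus), only congeneric between-species
    pairs are pooled; otherwise all between-species pairs.
    """
    sp_idx = _species_indices(dm, labels)
    species = sorted(sp_idx)
    vals: list[float] = []
    for k, sa in enumerate(species):
        for sb in species[k + 1 :]:
            if groups is not None:
                ga = {groups[dm.ids[i]] for i in sp_idx[sa]}
                gb = {groups[dm.ids[i]] for i in sp_idx[sb]}
                if not ga & gb:
                    continue
            vals.extend(_pair_values(dm, sp_idx[sa], sp_idx[sb]).tolist())
    return vals


@dataclass
class GapReport:
    """Barcoding-gap analysis of pooled intra- vs inter-specific distances.

    ``interval`` is (min(max_intra, min_inter), max(max_intra, min_inter));
    ``kind`` is 'overlap' when max_intra > min_inter, else 'gap' (a
    coincident boundary counts as a zero-width gap).  ``histogram`` bins
    both distributions over [0, max observed] at ``bin_width``.
    """

    intra_distances: list[float]
    inter_distances: list[float]
    max_intra: float
    min_inter: float
    interval: tuple[float, float]
    kind: str
    bin_width: float
    histogram: pd.DataFrame = field(repr=False, default=None)


def gap_report(
    intra: list[float], inter: list[float], bin_width: float = 0.005
) -> GapReport:
    """Build a :class:`GapReport` from pooled distance lists (order-invariant)."""
    if not len(intra) or not len(inter):
        raise ValueError("gap_report needs non-empty intra and inter distance lists")
    intra = sorted(float(x) for x in intra)
    inter = sorted(float(x) for x in inter)
    if any(np.isnan(intra)) or any(np.isnan(inter)):
        raise ValueError("gap_report input contains undefined distances")
    max_intra, min_inter = intra[-1], inter[0]
    lo, hi = sorted((max_intra, min_inter))
    top = max(intra[-1], inter[-1])
    n_bins = max(1, int(np.ceil(top / bin_width))) if top > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width
    hist = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "intra_count": np.histogram(intra, bins=edges)[0],
            "inter_count": np.histogram(inter, bins=edges)[0],
        }
    )
    return GapReport(
        intra_distances=intra,
        inter_distances=inter,
        max_intra=max_intra,
        min_inter=min_inter,
        interval=(lo, hi),
        kind="overlap" if max_intra > min_inter else "gap",
        bin_width=bin_width,
        histogram=hist,
    )


def prune_synonyms(
    dm: DistanceMatrix,
    labels: dict[str, str],
    genera: dict[str, str],
    threshold: float = 0.002,
) -> tuple[list[tuple[str, str, float]], dict[str, str]]:
    """Flag likely-synonymous congeneric species pairs and filter the labels.

    Congeneric species pairs whose mean between-species distance is strictly
    below ``threshold`` (default 0.002 substitutions/site) are flagged; both
    members of every flagged pair are excluded from the returned filtered
    seq_id -> species map.  The input map is untouched.
    """
    sp_idx = _species_indices(dm, labels)
    sp_genus = {}
    for sp, idx in sp_idx.items():
        g = {genera[dm.ids[i]] for i in idx if dm.ids[i] in genera}
        sp_genus[sp] = sorted(g)[0] if g else ""
    flagged: list[tuple[str, str, float]] = []
    removed: set[str] = set()
    species = sorted(sp_idx)
    for k, sa in enumerate(species):
        for sb in species[k + 1 :]:
            if sp_genus[sa] != sp_genus[sb]:
                continue
            vals = _pair_values(dm, sp_idx[sa], sp_idx[sb])
            if len(vals) and float(vals.mean()) < threshold:
                flagged.append((sa, sb, float(vals.mean())))
                removed.update((sa, sb))
    filtered = {sid: sp for sid, sp in labels.items() if sp not in removed}
    return flagged, filtered
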
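"""The tag-barcode method: per-species hypervariable sites and their use.

Within a species, some alignment columns are hypervariable: more than 30%
of that species' residues differ from the within-species consensus.  Such
columns inflate intraspecific divergence without carrying information that
separates the species from its congeners, so the intra- and inter-specific
distance distributions overlap and distance-based identification turns
ambiguous.

The tag of a species is the sorted list of its hypervariable alignment
positions (1-based, on the standard barcode coordinates).  The method then
applies an asymmetric rule:

* intraspecific distances of species S are recomputed with S's tag columns
  removed (shorter sequences, lower divergence);
* interspecific distances always use the full alignment (tags retained),
  so they are bit-identical to the unadjusted values.

Removing the overlap between the two distributions restores a barcoding
gap and raises best-close-match identification success.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tagbarcode.distance import DistanceMatrix, _pair_distance_codes, distance_matrix
from tagbarcode.divstats import GapReport, gap_report, inter_distances, intra_distances
from tagbarcode.identify import MatchOutcome, _score_query
from tagbarcode.seqio import BarcodeAlignment

__all__ = [
    "TagSet",
    "site_variability",
    "discover_tags",
    "tag_adjusted_intra",
    "tag_adjusted_inter",
    "tag_gap_analysis",
    "tag_best_close_match",
    "tag_identify",
]


@dataclass
class TagSet:
    """Per-species hypervariable alignment positions (1-based, sorted).

    ``variability`` retains the per-position within-species variability
    score for every processed species (NaN where fewer than two usable
    residues were available).
    """

    tags: dict[str, list[int]]
    threshold: float
    alignment_length: int
    variability: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def positions(self, species: str) -> list[int]:
        """Tag for a species; empty if the species was not processed."""
        return self.tags.get(species, [])

    def write_tsv(self, path) -> None:
        """TSV with columns species, threshold, positions (comma-separated)."""
        pd.DataFrame(
            [
                {
                    "species": sp,
                    "threshold": self.threshold,
                    "positions": ",".join(map(str, pos)),
                }
                for sp, pos in sorted(self.tags.items())
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, alignment_length: int = 0) -> "TagSet":
        df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
        tags = {
            row["species"]: [int(p) for p in row["positions"].split(",") if p]
            for _, row in df.iterrows()
        }
        thr = float(df["threshold"].iloc[0]) if len(df) else 0.30
        return cls(tags=tags, threshold=thr, alignment_length=alignment_length)


def site_variability(column_residues) -> float:
    """Within-species variability of one alignment column, in [0, 1).

    The fraction of the species' unambiguous residues (A/C/G/T) that differ
    from the column's modal residue; modal ties are broken alphabetically.
    Gaps and ambiguity codes count in neither numerator nor denominator.
    Returns NaN (undefined) when fewer than 2 usable residues remain.
    """
    counts = np.zeros(4, dtype=int)
    for ch in column_residues:
        i = "ACGT".find(ch.upper())
        if i >= 0:
            counts[i] += 1
    n = counts.sum()
    if n < 2:
        return float("nan")
    # argmax takes the first maximum: alphabetical tie-break for free
    return 1.0 - counts[np.argmax(counts)] / n


def _column_variability(codes: np.ndarray) -> np.ndarray:
    """Vectorized site_variability over all columns of a coded subalignment."""
    L = codes.shape[1]
    out = np.full(L, np.nan)
    for j in range(L):
        col = codes[:, j]
        counts = np.bincount(col[col != 255], minlength=4)[:4]
        n = counts.sum()
        if n >= 2:
            out[j] = 1.0 - counts.max() / n
    return out


def discover_tags(
    aln: BarcodeAlignment,
    labels: dict[str, str],
    threshold: float = 0.30,
    min_seqs: int = 3,
) -> TagSet:
    """Find each species' hypervariable positions (variability > threshold).

    Species with fewer than ``min_seqs`` sequences are skipped with a
    warning -- too few haplotypes make the variability estimate meaningless.
    Below ~10 sequences tags are still computed but flagged as imprecise.
    Output is invariant under reordering of sequences within a species.
    """
    codes = aln.to_array()
    by_species: dict[str, list[int]] = {}
    for i, sid in enumerate(aln.ids):
        by_species.setdefault(labels[sid], []).append(i)

    tags: dict[str, list[int]] = {}
    scores: dict[str, np.ndarray] = {}
    for sp in sorted(by_species):
        idx = by_species[sp]
        if len(idx) < min_seqs:
            warnings.warn(
                f"species {sp!r} has {len(idx)} sequence(s) < min_seqs={min_seqs}; skipped"
            )
            continue
        if len(idx) < 10:
            warnings.warn(
                f"species {sp!r} has only {len(idx)} sequences; tag positions are "
                "imprecise (10+ individuals recommended)"
            )
        var = _column_variability(codes[idx])
        with np.errstate(invalid="ignore"):
            pos = np.nonzero(var > threshold)[0] + 1
        tags[sp] = pos.tolist()
        scores[sp] = var
    return TagSet(
        tags=tags,
        threshold=threshold,
        alignment_length=aln.length,
        variability=scores,
    )


def _keep_columns(length: int, tag_positions: list[int]) -> np.ndarray:
    drop = set(tag_positions)
    bad = [p for p in drop if not 1 <= p <= length]
    if bad:
        raise ValueError(f"tag positions out of range 1..{length}: {sorted(bad)}")
    return np.array([j for j in range(length) if (j + 1) not in drop], dtype=int)


def tag_adjusted_intra(
    aln: BarcodeAlignment,
    labels: dict[str, str],
    tags: TagSet,
    model: str = "k2p",
) -> dict[str, list[float]]:
    """Intraspecific pairwise distances with each species' own tag removed.

    For species S, distances among S's sequences are recomputed on the
    alignment with S's tag columns deleted; other species' tags never touch
    S's intraspecific distances.  Undefined distances are dropped with a
    warning.  Species with < 2 sequences are omitted.
    """
    codes = aln.to_array()
    by_species: dict[str, list[int]] = {}
    for i, sid in enumerate(aln.ids):
        by_species.setdefault(labels[sid], []).append(i)
    out: dict[str, list[float]] = {}
    for sp in sorted(by_species):
        idx = by_species[sp]
        if len(idx) < 2:
            continue
        keep = _keep_columns(aln.length, tags.positions(sp))
        sub = codes[np.ix_(idx, keep)]
        vals = []
        n_undef = 0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d, _ = _pair_distance_codes(sub[a], sub[b], model)
                if np.isnan(d):
                    n_undef += 1
                else:
                    vals.append(float(d))
        if n_undef:
            warnings.warn(
                f"species {sp!r}: {n_undef} undefined tag-adjusted distance(s) dropped"
            )
        out[sp] = vals
    return out


def tag_adjusted_inter(
    aln: BarcodeAlignment,
    labels: dict[str, str],
    tags: TagSet,
    model: str = "k2p",
    genera: dict[str, str] | None = None,
) -> list[float]:
    """Interspecific distances under the tag rule: tags retained.

    Between-species distances always use the full alignment, so this is a
    definitional pass-through of the unadjusted interspecific distances
    (bit-identical).  ``tags`` is accepted only to make the asymmetry of the
    method explicit at the call site.
    """
    del tags  # retained by construction
    dm = distance_matrix(aln, model)
    return inter_distances(dm, labels, genera)


def tag_gap_analysis(
    aln: BarcodeAlignment,
    labels: dict[str, str],
    tags: TagSet,
    model: str = "k2p",
    bin_width: float = 0.005,
    genera: dict[str, str] | None = None,
) -> tuple[GapReport, GapReport]:
    """Barcoding-gap reports before and after tag adjustment.

    'Before' pools unadjusted intra- and inter-specific distances; 'after'
    pools tag-adjusted intraspecific distances with the same (retained)
    interspecific distances.  Requires >= 2 species with usable pairs.
    """
    if len(set(labels[i] for i in aln.ids)) < 2:
        raise ValueError("tag_gap_analysis needs at least 2 species")
    dm = distance_matrix(aln, model)
    intra_before = intra_distances(dm, labels)
    inter = inter_distances(dm, labels, genera)
    intra_after = [
        d for vals in tag_adjusted_intra(aln, labels, tags, model).values() for d in vals
    ]
    before = gap_report(intra_before, inter, bin_width)
    after = gap_report(intra_after, inter, bin_width)
    return before, after


def _adjusted_threshold(
    aln: BarcodeAlignment,
    labels: dict[str, str],
    tags: TagSet,
    model: str,
    coverage: float,
    method: str = "inverted_cdf",
) -> float:
    vals = [
        d for v in tag_adjusted_intra(aln, labels, tags, model).values() for d in v
    ]
    if not vals:
        raise ValueError("no intraspecific pairs: cannot set a tag-adjusted threshold")
    return float(np.quantile(np.asarray(vals), coverage, method=method))


def _tag_score_queries(
    query_codes: np.ndarray,
    query_ids: list[str],
    query_species: list[str],
    ref_codes: np.ndarray,
    ref_ids: list[str],
    ref_labels: dict[str, str],
    tags: TagSet,
    model: str,
    shortlist_threshold: float,
    adjusted_threshold: float,
    exclude_self: bool,
    tolerance: float,
) -> list[MatchOutcome]:
    """Shared engine for tag-aware identification.

    Step (ii): shortlist the candidate species whose nearest reference (full
    alignment, unadjusted distances) lies within ``shortlist_threshold``.
    Step (iii): recompute the query's distances to each shortlisted species
    S with S's tag columns removed, then apply best-close-match scoring to
    the pooled adjusted distances at ``adjusted_threshold``.
    """
    length = ref_codes.shape[1]
    by_species: dict[str, list[int]] = {}
    for j, rid in enumerate(ref_ids):
        by_species.setdefault(ref_labels[rid], []).append(j)
    keep_cols = {
        sp: _keep_columns(length, tags.positions(sp)) for sp in by_species
    }

    out = []
    for qi, qid in enumerate(query_ids):
        # step (ii): unadjusted nearest-reference distance per species
        if np.isinf(shortlist_threshold):
            shortlist = [
                sp
                for sp, idx in by_species.items()
                if not (exclude_self and len(idx) == 1 and ref_ids[idx[0]] == qid)
            ]
        else:
            shortlist = []
            for sp, idx in by_species.items():
                best = np.inf
                for j in idx:
                    if exclude_self and ref_ids[j] == qid:
                        continue
                    d, _ = _pair_distance_codes(query_codes[qi], ref_codes[j], model)
                    if not np.isnan(d):
                        best = min(best, d)
                if best <= shortlist_threshold:
                    shortlist.append(sp)
        if not shortlist:
            out.append(MatchOutcome(qid, "unidentified", float("nan"), ()))
            continue
        # step (iii): adjusted distances to shortlisted species
        dists, sps = [], []
        for sp in shortlist:
            keep = keep_cols[sp]
            q = query_codes[qi][keep]
            for j in by_species[sp]:
                if exclude_self and ref_ids[j] == qid:
                    continue
                d, _ = _pair_distance_codes(q, ref_codes[j][keep], model)
                dists.append(d)
                sps.append(sp)
        out.append(
            _score_query(
                qid,
                query_species[qi],
                np.asarray(dists, dtype=float),
                np.asarray(sps),
                threshold=adjusted_threshold,
                tolerance=tolerance,
            )
        )
    return out


def tag_best_close_match(
    aln: BarcodeAlignment,
    labels: dict[str, str],
    tags: TagSet,
    model: str = "k2p",
    coverage: float = 0.95,
    shortlist_threshold: float | None = None,
    adjusted_threshold: float | None = None,
    tolerance: float = 0.0,
) -> tuple[list[MatchOutcome], float]:
    """Leave-one-out best close match on tag-adjusted distances.

    Mirrors :func:`tagbarcode.identify.best_close_match` but with the tag
    rule: every candidate species is compared on the alignment minus its own
    tag columns, and the identification threshold is recomputed from the
    tag-adjusted intraspecific distances at the given coverage (pass
    ``adjusted_threshold`` to override).  No shortlist is applied by default
    (``shortlist_threshold=inf``): this is the retrospective re-evaluation
    of the whole library after tagging, not the prospective unknown-query
    workflow of :func:`tag_identify`.

    Returns the outcomes and the adjusted threshold used.
    """
    if shortlist_threshold is None:
        shortlist_threshold = float("inf")
    if adjusted_threshold is None:
        adjusted_threshold = _adjusted_threshold(aln, labels, tags, model, coverage)
    codes = aln.to_array()
    species = [labels[i] for i in aln.ids]
    outcomes = _tag_score_queries(
        codes,
        list(aln.ids),
        species,
        codes,
        list(aln.ids),
        labels,
        tags,
        model,
        shortlist_threshold,
        adjusted_threshold,
        exclude_self=True,
        tolerance=tolerance,
    )
    return outcomes, adjusted_threshold


def tag_identify(
    queries: BarcodeAlignment,
    reference: BarcodeAlignment,
    labels: dict[str, str],
    tags: TagSet,
    model: str = "k2p",
    coverage: float = 0.95,
    shortlist_threshold: float | None = None,
    adjusted_threshold: float | None = None,
    query_labels: dict[str, str] | None = None,
    tolerance: float = 0.0,
) -> tuple[list[MatchOutcome], float]:
    """Tag-aware identification of external queries against a reference library.

    Queries must be aligned to the reference coordinates (same length).
    Workflow: (ii) shortlist species whose nearest reference is within the
    unadjusted intraspecific threshold; (iii) rescore the query against each
    shortlisted species with that species' tag columns removed, at a
    threshold recomputed from tag-adjusted intraspecific distances.

    ``query_labels`` (seq_id -> true species) enables success/misidentified
    scoring; without it, outcomes score against an empty species name, so
    only the assigned ``matched_species`` and ambiguous/unidentified states
    are meaningful.
    """
    from tagbarcode.identify import intraspecific_threshold

    if queries.length != reference.length:
        raise ValueError(
            f"queries are not aligned to reference coordinates "
            f"({queries.length} vs {reference.length} columns)"
        )
    dm = distance_matrix(reference, model)
    if shortlist_threshold is None:
        shortlist_threshold = intraspecific_threshold(dm, labels, coverage)
    if adjusted_threshold is None:
        adjusted_threshold = _adjusted_threshold(
            reference, labels, tags, model, coverage
        )
    qlabels = query_labels or {}
    outcomes = _tag_score_queries(
        queries.to_array(),
        list(queries.ids),
        [qlabels.get(i, "") for i in queries.ids],
        reference.to_array(),
        list(reference.ids),
        labels,
        tags,
        model,
        shortlist_threshold,
        adjusted_threshold,
        exclude_self=False,
        tolerance=tolerance,
    )
    return outcomes, adjusted_threshold
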
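"""The tag-barcode method: discovery, adjusted divergences, identification."""

import math

import numpy as np
import pytest

from tagbarcode.distance import distance_matrix
from tagbarcode.divstats import inter_distances, intra_distances
from tagbarcode.synth import SynthConfig, generate
from tagbarcode.tags import (
    TagSet,
    discover_tags,
    site_variability,
    tag_adjusted_inter,
    tag_adjusted_intra,
    tag_best_close_match,
    tag_gap_analysis,
    tag_identify,
)
from tests.conftest import make_alignment, mutate_at


@pytest.mark.parametrize(
    "column,expected",
    [
        ("A" * 6 + "C" * 4, 0.4),  # brute-force count: 4 of 10 off-modal
        ("A" * 10, 0.0),
        ("A" * 5 + "G" * 5, 0.5),  # tie broken alphabetically: modal A
        ("AG", 0.5),
        ("ACGT", 0.75),
    ],
)
def test_site_variability_values(column, expected):
    assert site_variability(column) == pytest.approx(expected)


def test_site_variability_excludes_gaps_and_ambiguity():
    assert site_variability("AA--NNRY") == 0.0  # two usable A's
    assert math.isnan(site_variability("A-N"))  # fewer than 2 usable
    assert math.isnan(site_variability(""))


def _species_block(base, hv_patterns):
    """10 sequences of one species; hv_patterns maps 1-based position ->
    list of residues per individual."""
    seqs = []
    for k in range(10):
        changes = {pos: states[k] for pos, states in hv_patterns.items()}
        seqs.append(mutate_at(base, changes))
    return seqs


def test_discover_tags_thresholding():
    base = "A" * 40
    # column 12: 4/10 non-modal (0.4 > 0.3); column 30: 1/10 (0.1)
    hv = {12: list("GGGGAAAAAA"), 30: list("GAAAAAAAAA")}
    seqs = _species_block(base, hv)
    entries = [(f"x{k}", "X", s) for k, s in enumerate(seqs)]
    entries += [(f"y{k}", "Y", "C" * 40) for k in range(10)]
    aln = make_alignment(entries)
    tags = discover_tags(aln, aln.species_labels())
    assert tags.tags["X"] == [12]
    assert tags.tags["Y"] == []
    assert tags.variability["X"][11] == pytest.approx(0.4)
    assert tags.variability["X"][29] == pytest.approx(0.1)


def test_discover_tags_threshold_one_yields_empty():
    aln, _ = generate(SynthConfig(species_per_genus=2, individuals_per_species=5,
                                  length=60, seed=2))
    tags = discover_tags(aln, aln.species_labels(), threshold=1.0)
    assert all(not v for v in tags.tags.values())


def test_discover_tags_min_seqs_skip_and_warning():
    entries = [("a1", "A", "ACGT" * 3), ("a2", "A", "ACGT" * 3),
               ("b1", "B", "ACGT" * 3), ("b2", "B", "ACGT" * 3), ("b3", "B", "ACGT" * 3)]
    aln = make_alignment(entries)
    with pytest.warns(UserWarning, match="min_seqs"):
        tags = discover_tags(aln, aln.species_labels(), min_seqs=3)
    assert "A" not in tags.tags and "B" in tags.tags


def test_discover_tags_invariant_under_reordering():
    aln, _ = generate(SynthConfig(species_per_genus=3, individuals_per_species=6,
                                  length=120, seed=9,
                                  hv_species=("G01_sp01",), hv_n_columns=4,
                                  hv_variability=0.5))
    labels = aln.species_labels()
    tags1 = discover_tags(aln, labels)
    rng = np.random.default_rng(0)
    order = list(aln.ids)
    rng.shuffle(order)
    tags2 = discover_tags(aln.subset(order), labels)
    assert tags1.tags == tags2.tags


def test_tagset_tsv_roundtrip(tmp_path):
    ts = TagSet(tags={"A": [7, 49, 61], "B": []}, threshold=0.3, alignment_length=658)
    path = tmp_path / "tags.tsv"
    ts.write_tsv(path)
    back = TagSet.read_tsv(path, alignment_length=658)
    assert back.tags == ts.tags
    assert back.threshold == 0.3


def test_tag_adjusted_intra_removes_only_focal_tag():
    base = "A" * 10
    aln = make_alignment(
        [("a1", "A", base), ("a2", "A", mutate_at(base, {5: "G"})),
         ("b1", "B", "C" * 10), ("b2", "B", "C" * 10)]
    )
    labels = aln.species_labels()
    tags = TagSet(tags={"A": [5], "B": [1, 2]}, threshold=0.3, alignment_length=10)
    adj = tag_adjusted_intra(aln, labels, tags)
    assert adj["A"] == [0.0]  # only difference sat at A's tag position
    assert adj["B"] == [0.0]


def test_empty_tag_is_identity():
    aln, _ = generate(SynthConfig(species_per_genus=3, individuals_per_species=4,
                                  length=200, seed=4))
    labels = aln.species_labels()
    empty = TagSet(tags={}, threshold=0.3, alignment_length=aln.length)
    adj = tag_adjusted_intra(aln, labels, empty)
    dm = distance_matrix(aln)
    assert sorted(d for v in adj.values() for d in v) == sorted(
        intra_distances(dm, labels)
    )


def test_tag_positions_out_of_range_rejected():
    aln = make_alignment([("a1", "A", "ACGT"), ("a2", "A", "ACGT")])
    bad = TagSet(tags={"A": [9]}, threshold=0.3, alignment_length=4)
    with pytest.raises(ValueError, match="out of range"):
        tag_adjusted_intra(aln, aln.species_labels(), bad)


def test_inter_distances_bit_identical_after_tagging():
    aln, _ = generate(SynthConfig(species_per_genus=4, individuals_per_species=5,
                                  length=300, seed=5,
                                  hv_species=("G01_sp01", "G01_sp02"),
                                  hv_n_columns=6, hv_variability=0.5))
    labels = aln.species_labels()
    tags = discover_tags(aln, labels)
    dm = distance_matrix(aln)
    plain = inter_distances(dm, labels)
    tagged = tag_adjusted_inter(aln, labels, tags)
    assert tagged == plain  # bit-identical: tags are retained between species


def test_adjusted_intra_shrinks_with_injected_columns():
    aln, _ = generate(SynthConfig(species_per_genus=4, individuals_per_species=8,
                                  length=400, seed=6,
                                  hv_species=("G01_sp01", "G01_sp02"),
                                  hv_n_columns=8, hv_variability=0.5))
    labels = aln.species_labels()
    tags = discover_tags(aln, labels)
    dm = distance_matrix(aln)
    plain = np.mean(intra_distances(dm, labels))
    adj = np.mean([d for v in tag_adjusted_intra(aln, labels, tags).values() for d in v])
    assert adj < plain
    # adjusted alignment length shrinks by exactly the tag size
    for sp, pos in tags.tags.items():
        assert aln.length - len(pos) == aln.drop_columns(pos).length


def test_tag_gap_analysis_flips_engineered_overlap(overlap_fixture):
    labels = overlap_fixture.species_labels()
    tags = discover_tags(overlap_fixture, labels)
    assert tags.tags["SpA"] == [10, 30, 50, 70]
    assert tags.tags["SpB"] == []
    before, after = tag_gap_analysis(overlap_fixture, labels, tags)
    assert before.kind == "overlap"
    assert after.kind == "gap"
    assert before.max_intra > before.min_inter
    assert after.max_intra == 0.0
    assert after.inter_distances == before.inter_distances


def test_tag_gap_analysis_identity_without_hypervariable_sites():
    aln, _ = generate(SynthConfig(species_per_genus=3, individuals_per_species=5,
                                  length=250, seed=8))
    labels = aln.species_labels()
    tags = discover_tags(aln, labels)
    before, after = tag_gap_analysis(aln, labels, tags)
    if all(not v for v in tags.tags.values()):
        assert before.intra_distances == after.intra_distances
    assert before.inter_distances == after.inter_distances


def test_tag_gap_analysis_needs_two_species():
    aln = make_alignment([("a1", "A", "ACGT" * 5), ("a2", "A", "ACGT" * 5)])
    tags = TagSet(tags={}, threshold=0.3, alignment_length=20)
    with pytest.raises(ValueError, match="2 species"):
        tag_gap_analysis(aln, aln.species_labels(), tags)


def test_tag_identify_query_matching_reference(overlap_fixture):
    labels = overlap_fixture.species_labels()
    tags = discover_tags(overlap_fixture, labels)
    queries = overlap_fixture.subset(["A_i1"])
    outcomes, _ = tag_identify(
        queries, overlap_fixture, labels, tags, query_labels={"A_i1": "SpA"}
    )
    assert outcomes[0].outcome == "success"


def test_tag_identify_rescues_tag_position_variants(overlap_fixture):
    """A query differing from its species only at that species' tag columns
    identifies cleanly once the tag is dropped."""
    labels = overlap_fixture.species_labels()
    tags = discover_tags(overlap_fixture, labels)
    base = overlap_fixture.record("A_i1").residues
    variant = mutate_at(base, {10: "T", 30: "G", 50: "C", 70: "A"})
    queries = make_alignment([("q1", "SpA", variant)])
    outcomes, _ = tag_identify(
        queries, overlap_fixture, labels, tags,
        shortlist_threshold=0.06, query_labels={"q1": "SpA"},
    )
    assert outcomes[0].outcome == "success"
    assert outcomes[0].best_distance == 0.0


def test_tag_identify_far_query_unidentified(overlap_fixture):
    labels = overlap_fixture.species_labels()
    tags = discover_tags(overlap_fixture, labels)
    far = "T" * overlap_fixture.length
    queries = make_alignment([("q1", "SpZ", far)])
    outcomes, _ = tag_identify(queries, overlap_fixture, labels, tags,
                               query_labels={"q1": "SpZ"})
    assert outcomes[0].outcome == "unidentified"


def test_tag_identify_rejects_unaligned_queries(overlap_fixture):
    labels = overlap_fixture.species_labels()
    tags = discover_tags(overlap_fixture, labels)
    queries = make_alignment([("q1", "SpA", "ACGT")])
    with pytest.raises(ValueError, match="aligned"):
        tag_identify(queries, overlap_fixture, labels, tags)


def test_tag_best_close_match_improves_on_inflated_species():
    """Leave-one-out re-evaluation: under-sampled species with injected
    hypervariable columns fail best close match before tagging and are
    recovered after."""
    from tagbarcode.identify import best_close_match, intraspecific_threshold, summarize

    hv = tuple(f"G01_sp{i:02d}" for i in (1, 2, 3))
    aln, _ = generate(SynthConfig(species_per_genus=12, individuals_per_species=12,
                                  hv_individuals=6, length=658,
                                  target_intra=0.002, target_inter=0.05,
                                  hv_species=hv, hv_n_columns=10,
                                  hv_variability=0.5, seed=13))
    labels = aln.species_labels()
    dm = distance_matrix(aln)
    thr = intraspecific_threshold(dm, labels)
    plain = summarize(best_close_match(dm, labels, thr))
    tags = discover_tags(aln, labels)
    outcomes, adj_thr = tag_best_close_match(aln, labels, tags)
    tagged = summarize(outcomes)
    assert plain.rates["success"] < tagged.rates["success"]
    assert adj_thr <= thr
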
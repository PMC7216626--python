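import numpy as np
import pytest

from mitopop.alleles import extract_cds
from mitopop.diversity import Alignment
from mitopop.introgression import (MarkerCatalogue, Marker, MarkerState,
                                   call_segments, derive_markers,
                                   foreign_fraction_vs_nuclear, paint_isolate)
from mitopop.sim import (CANONICAL_GENES, SimConfig, plant_introgressions,
                         simulate_donor, simulate_population,
                         simulate_reference)


def _aln(gene, rows):
    return Alignment.from_sequences(gene, {f"s{i}": r for i, r in enumerate(rows)})


def test_marker_from_major_allele_difference_with_frequencies():
    sp1 = {"g": _aln("g", ["A", "A", "A", "A", "A", "G"])}  # {A:5, G:1}
    sp2 = {"g": _aln("g", ["G", "G", "G", "G"])}
    cat = derive_markers(sp1, sp2, ["g"])
    assert len(cat) == 1
    m = cat.markers[0]
    assert (m.allele1, m.allele2) == ("A", "G")
    assert m.af1 == pytest.approx(5 / 6)
    assert m.af2 == pytest.approx(1.0)


def test_position_with_equal_majors_is_dropped():
    sp1 = {"g": _aln("g", ["AT", "AT", "GT"])}   # major A at 0
    sp2 = {"g": _aln("g", ["AT", "CT"])}         # major A (tie A<C) at 0
    cat = derive_markers(sp1, sp2, ["g"])
    assert len(cat) == 0


def test_species_swap_symmetry():
    rng = np.random.default_rng(53)
    L = 200
    base = rng.choice(list("ACGT"), size=L)
    donor = base.copy()
    flip = rng.choice(L, size=20, replace=False)
    for k in flip:
        donor[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[donor[k]]
    sp1 = {"g": _aln("g", ["".join(base)] * 3)}
    sp2 = {"g": _aln("g", ["".join(donor)] * 2)}
    cat_ab = derive_markers(sp1, sp2, ["g"])
    cat_ba = derive_markers(sp2, sp1, ["g"])
    assert [(m.gene, m.offset) for m in cat_ab.markers] == \
           [(m.gene, m.offset) for m in cat_ba.markers]
    assert all(a.allele1 == b.allele2 and a.allele2 == b.allele1
               for a, b in zip(cat_ab.markers, cat_ba.markers))


def _toy_catalogue(n=8, gap=10, gene="g", length=None):
    markers = [Marker(gene=gene, offset=gap * (k + 1), allele1="A",
                      af1=1.0, allele2="G", af2=1.0) for k in range(n)]
    return MarkerCatalogue(markers=markers, gene_order=[gene],
                           gene_lengths={gene: length or gap * (n + 2)})


def test_painting_states_for_reference_donor_and_other():
    cat = _toy_catalogue(n=4)
    ref_seq = "A" * 100
    donor_seq = list("A" * 100)
    for m in cat.markers:
        donor_seq[m.offset] = "G"
    other_seq = list(ref_seq)
    other_seq[cat.markers[0].offset] = "T"
    other_seq[cat.markers[1].offset] = "N"
    assert all(s is MarkerState.CONSPECIFIC for s in
               paint_isolate("r", {"g": ref_seq}, cat).states)
    assert all(s is MarkerState.FOREIGN for s in
               paint_isolate("d", {"g": "".join(donor_seq)}, cat).states)
    states = paint_isolate("o", {"g": "".join(other_seq)}, cat).states
    assert states[0] is MarkerState.OTHER and states[1] is MarkerState.MISSING


def test_segment_calling_with_midpoint_boundaries():
    # states S S F F F F F S at offsets 10..80
    cat = _toy_catalogue(n=8)
    states = [MarkerState.CONSPECIFIC] * 2 + [MarkerState.FOREIGN] * 5 + \
             [MarkerState.CONSPECIFIC]
    from mitopop.introgression import MarkerPainting
    segs = call_segments(MarkerPainting("x", states), cat, min_run=5)
    assert len(segs) == 1
    s = segs[0]
    assert s.n_foreign_markers == 5
    assert s.start_boundary == pytest.approx((20 + 30) / 2)
    assert s.end_boundary == pytest.approx((70 + 80) / 2)


def test_alternating_states_give_no_segment():
    cat = _toy_catalogue(n=6)
    from mitopop.introgression import MarkerPainting
    states = [MarkerState.CONSPECIFIC, MarkerState.FOREIGN] * 3
    assert call_segments(MarkerPainting("x", states), cat, min_run=5) == []


def test_missing_markers_are_transparent_to_runs():
    cat = _toy_catalogue(n=8)
    from mitopop.introgression import MarkerPainting
    F, S, M = MarkerState.FOREIGN, MarkerState.CONSPECIFIC, MarkerState.MISSING
    states = [S, F, F, M, F, F, F, S]
    segs = call_segments(MarkerPainting("x", states), cat, min_run=5)
    assert len(segs) == 1 and segs[0].n_foreign_markers == 5
    # boundaries skip the missing marker when looking for flanks
    assert segs[0].start_boundary == pytest.approx((10 + 20) / 2)
    assert segs[0].end_boundary == pytest.approx((70 + 80) / 2)


def test_min_run_one_covers_every_foreign_marker():
    cat = _toy_catalogue(n=6)
    from mitopop.introgression import MarkerPainting
    F, S = MarkerState.FOREIGN, MarkerState.CONSPECIFIC
    states = [S, F, S, F, F, S]
    segs = call_segments(MarkerPainting("x", states), cat, min_run=1)
    covered = set()
    for s in segs:
        covered.update(range(s.first_marker, s.last_marker + 1))
    assert covered == {1, 3, 4}
    # segments never overlap
    ordered = sorted(segs, key=lambda s: s.start_boundary)
    assert all(a.end_boundary <= b.start_boundary
               for a, b in zip(ordered, ordered[1:]))


def test_run_touching_catalogue_end_extends_to_cds_end():
    cat = _toy_catalogue(n=6)
    from mitopop.introgression import MarkerPainting
    F, S = MarkerState.FOREIGN, MarkerState.CONSPECIFIC
    segs = call_segments(MarkerPainting("x", [S] + [F] * 5), cat, min_run=5)
    assert segs[0].end_boundary == cat.total_length


def test_planted_half_gene_recovered_within_marker_gap():
    """End-to-end: plant a half-gene donor block, derive markers from the
    species panels, call segments, compare boundaries against truth."""
    cfg = SimConfig(seed=61, n_lineages=4, isolates_per_lineage=3,
                    petite_fraction=0.0, admixed_fraction=0.0)
    ref = simulate_reference(cfg)
    pop, _ = simulate_population(ref, cfg)
    donor = simulate_donor(cfg)
    half = 800  # half of COX1's 1605-nt CDS
    target = pop[0].isolate_id
    planted, truth = plant_introgressions(pop, donor, [(target, "COX1", 0, half)])

    genes = {g: ref.spliced_cds(g) for g in CANONICAL_GENES}
    sp1 = {g: Alignment.from_sequences(
        g, {"REF": genes[g], **{x.isolate_id: x.spliced_cds(g) for x in pop[1:]}})
        for g in CANONICAL_GENES}
    sp2 = {g: Alignment.from_sequences(g, {"DONOR": donor.spliced_cds(g)})
           for g in CANONICAL_GENES}
    cat = derive_markers(sp1, sp2, list(CANONICAL_GENES))
    assert len(cat) > 50  # ~6.6 kb at 2% divergence

    cds_map = extract_cds(planted[0], genes)
    painting = paint_isolate(target, cds_map, cat)
    segs = call_segments(painting, cat, min_run=5)
    cox1_markers = [(k, m) for k, m in enumerate(cat.markers) if m.gene == "COX1"]
    inside = [k for k, m in cox1_markers if m.offset < half]
    assert len(inside) >= 5
    assert len(segs) >= 1
    # the called segment containing COX1 must cover exactly the inside markers
    seg = max(segs, key=lambda s: s.n_foreign_markers)
    pos = cat.concat_positions()
    gene_base = sum(cat.gene_lengths[g] for g in cat.gene_order
                    if cat.gene_order.index(g) < cat.gene_order.index("COX1"))
    true_end = gene_base + half
    # boundary error bounded by the local inter-marker gap
    last_inside = max(inside)
    next_marker = last_inside + 1
    gap = pos[next_marker] - pos[last_inside]
    assert abs(seg.end_boundary - true_end) <= gap


def test_unplanted_isolates_yield_no_calls():
    cfg = SimConfig(seed=61, n_lineages=4, isolates_per_lineage=3,
                    petite_fraction=0.0, admixed_fraction=0.0)
    ref = simulate_reference(cfg)
    pop, _ = simulate_population(ref, cfg)
    donor = simulate_donor(cfg)
    genes = {g: ref.spliced_cds(g) for g in CANONICAL_GENES}
    sp1 = {g: Alignment.from_sequences(
        g, {"REF": genes[g], **{x.isolate_id: x.spliced_cds(g) for x in pop}})
        for g in CANONICAL_GENES}
    sp2 = {g: Alignment.from_sequences(g, {"DONOR": donor.spliced_cds(g)})
           for g in CANONICAL_GENES}
    cat = derive_markers(sp1, sp2, list(CANONICAL_GENES))
    for x in pop:
        painting = paint_isolate(x.isolate_id, extract_cds(x, genes), cat)
        assert call_segments(painting, cat, min_run=5) == []


def test_foreign_fraction_extremes_and_null_correlation():
    cat = _toy_catalogue(n=10)
    ref_seq = "A" * 130
    donor_seq = list(ref_seq)
    for m in cat.markers:
        donor_seq[m.offset] = "G"
    p_ref = paint_isolate("ref", {"g": ref_seq}, cat)
    p_don = paint_isolate("don", {"g": "".join(donor_seq)}, cat)
    assert p_ref.fraction_foreign() == 0.0
    assert p_don.fraction_foreign() == 1.0

    rng = np.random.default_rng(67)
    paintings = []
    counts = {}
    for i in range(20):
        seq = list(ref_seq)
        for m in cat.markers:
            if rng.random() < 0.3:
                seq[m.offset] = "G"
        paintings.append(paint_isolate(f"i{i}", {"g": "".join(seq)}, cat))
        counts[f"i{i}"] = int(rng.integers(0, 50))
    table, rho, p = foreign_fraction_vs_nuclear(paintings, counts,
                                                n_permutations=499, seed=5)
    assert len(table) == 20
    assert p > 0.05  # independent simulation stays inside the null band
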
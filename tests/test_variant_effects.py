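import math

import numpy as np
import pytest

from spliceinfo.infomodel import (
    BASES,
    Origin,
    SiteKind,
    SiteScore,
    reverse_complement,
    score_site,
)
from spliceinfo.synthetic import plant_variant
from spliceinfo.variant_effects import (
    CandidateFlags,
    Classification,
    CriteriaConfig,
    Exon,
    GeneModel,
    LengthHistogram,
    Transcript,
    ValidationError,
    Variant,
    VariantSpliceEffect,
    candidate_filter,
    classify_effect,
    effects_to_dataframe,
    evaluate_variant,
    exon_definition_total,
    extract_window,
    natural_junctions,
    natural_sites_for,
)


def make_effect(origin, delta, ri_final, het=None, **kw):
    site = SiteScore("chr1", 100, "+", SiteKind.DONOR, ri_final - delta, origin)
    return VariantSpliceEffect(
        variant=Variant("chr1", 101, "A", "G", het=het),
        site=site,
        ri_initial=ri_final - delta,
        ri_final=ri_final,
        delta_ri=delta,
        fold=None,
        distance_to_natural=0 if origin == Origin.NATURAL else 20,
        **kw,
    )


class TestGeometry:
    def test_three_exon_transcript_has_two_donors_two_acceptors(self, locus):
        sites = natural_sites_for(locus.model, locus.genome, locus.matrices)
        kinds = [s.site_kind for s in sites]
        assert kinds.count(SiteKind.DONOR) == 2
        assert kinds.count(SiteKind.ACCEPTOR) == 2

    def test_scores_equal_independently_sliced_windows(self, locus):
        # oracle: slice the genome by hand from the junction coordinates
        seq = locus.genome["chrS"]
        for site in natural_sites_for(locus.model, locus.genome, locus.matrices):
            m = locus.matrices[site.site_kind]
            s = site.junction_position + m.window_start
            assert site.ri == pytest.approx(
                score_site(m, seq[s : s + m.length]), abs=1e-9
            )

    def test_minus_strand_window_is_reverse_complement_of_mirror(self, locus):
        genome = locus.genome
        n = len(genome["chrS"])
        mirrored = {"chrS": reverse_complement(genome["chrS"])}
        for site in locus.natural_sites:
            m = locus.matrices[site.site_kind]
            plus = extract_window(genome, "chrS", site.junction_position, "+",
                                  m.window_start, m.length)
            minus = extract_window(mirrored, "chrS", n - 1 - site.junction_position,
                                   "-", m.window_start, m.length)
            assert plus == minus

    def test_minus_strand_junction_enumeration(self):
        exons = (Exon("c", 100, 200), Exon("c", 300, 400))
        gm = GeneModel("g", "-", (Transcript("t", exons),))
        got = dict(((kind, j) for _, j, kind in natural_junctions(gm)))
        # transcript runs right-to-left: donor just left of exon at 300,
        # acceptor at the rightmost base of the exon ending at 200
        assert (SiteKind.DONOR, 299) in {(k, j) for _, j, k in natural_junctions(gm)}
        assert (SiteKind.ACCEPTOR, 199) in {(k, j) for _, j, k in natural_junctions(gm)}

    def test_out_of_bounds_window_raises(self, locus):
        m = locus.matrices[SiteKind.ACCEPTOR]
        with pytest.raises(ValidationError):
            extract_window(locus.genome, "chrS", 2, "+", m.window_start, m.length)
        with pytest.raises(ValidationError):
            extract_window(locus.genome, "nope", 100, "+", m.window_start, m.length)


class TestEvaluateVariant:
    def test_single_column_identity(self, locus):
        planted = plant_variant(locus, locus.natural_sites[0], target_delta=-2.0)
        effects = evaluate_variant(
            planted.variant, locus.model, locus.genome, locus.matrices
        )
        natural = [e for e in effects if e.site.origin == Origin.NATURAL]
        assert len(natural) == 1
        assert natural[0].delta_ri == pytest.approx(planted.delta_ri, abs=1e-12)
        assert natural[0].ri_initial == pytest.approx(planted.ri_initial, abs=1e-9)

    def test_variant_outside_all_windows_is_empty(self, locus):
        seq = locus.genome["chrS"]
        ref = seq[10]
        variant = Variant("chrS", 11, ref, "A" if ref != "A" else "C")
        assert evaluate_variant(
            variant, locus.model, locus.genome, locus.matrices
        ) == []

    def test_reference_mismatch_raises(self, locus):
        j = locus.natural_sites[0].junction_position
        base = locus.genome["chrS"][j]
        wrong = "A" if base != "A" else "C"
        other = "G" if base not in "GT" else "T"
        with pytest.raises(ValidationError, match="reference mismatch"):
            evaluate_variant(
                Variant("chrS", j + 1, wrong, other),
                locus.model, locus.genome, locus.matrices,
            )

    def test_cryptic_site_reported_when_natural_weakened(self, cryptic_locus):
        locus = cryptic_locus
        strong_cryptic = locus.cryptic_sites[0]  # 12 nt past the first donor
        planted = plant_variant(locus, locus.natural_sites[0], target_delta=-6.0)
        effects = evaluate_variant(
            planted.variant, locus.model, locus.genome, locus.matrices
        )
        cryptic = [e for e in effects
                   if e.site.origin == Origin.CRYPTIC
                   and e.site.junction_position == strong_cryptic.junction_position]
        assert cryptic, "strong neighbouring cryptic site not reported"
        eff = cryptic[0]
        assert eff.classification == Classification.CRYPTIC_ACTIVATED
        natural = [e for e in effects if e.site.origin == Origin.NATURAL][0]
        assert eff.ri_final >= natural.ri_final  # exceeds the weakened natural

    def test_pseudoexon_candidate_deep_in_intron(self, cryptic_locus):
        locus = cryptic_locus
        weak_deep = locus.cryptic_sites[1]  # ~1 bit, 100 nt into the intron
        planted = plant_variant(locus, weak_deep, target_delta=+2.0)
        assert planted.ri_initial < 1.6 <= planted.ri_final
        effects = evaluate_variant(
            planted.variant, locus.model, locus.genome, locus.matrices
        )
        hits = [e for e in effects
                if e.site.junction_position == weak_deep.junction_position]
        assert hits
        assert hits[0].classification == Classification.PSEUDOEXON_CANDIDATE

    def test_no_cryptic_above_ri_min_never_emits_cryptic_activated(self, locus):
        # the plain locus has its background suppressed below ri_min
        for target in (-2.0, -6.0, -0.5):
            for site in locus.natural_sites:
                planted = plant_variant(locus, site, target_delta=target)
                effects = evaluate_variant(
                    planted.variant, locus.model, locus.genome, locus.matrices
                )
                for e in effects:
                    if e.site.origin == Origin.CRYPTIC:
                        assert e.classification != Classification.CRYPTIC_ACTIVATED or \
                            e.ri_final >= 1.6

    def test_strand_invariance(self, locus):
        planted = plant_variant(locus, locus.natural_sites[0], target_delta=-2.0)
        genome = locus.genome
        n = len(genome["chrS"])
        mirrored_genome = {"chrS": reverse_complement(genome["chrS"])}
        tx = locus.model.transcripts[0]
        mirrored_exons = tuple(
            Exon("chrS", n - e.end, n - e.start) for e in reversed(tx.exons)
        )
        mirrored_model = GeneModel(
            "geneS", "-", (Transcript("t1", mirrored_exons),)
        )
        v = planted.variant
        mirrored_variant = Variant(
            "chrS", n - v.pos0, reverse_complement(v.ref), reverse_complement(v.alt),
        )
        fwd = evaluate_variant(v, locus.model, genome, locus.matrices)
        rev = evaluate_variant(
            mirrored_variant, mirrored_model, mirrored_genome, locus.matrices
        )
        fwd_deltas = sorted(round(e.delta_ri, 9) for e in fwd)
        rev_deltas = sorted(round(e.delta_ri, 9) for e in rev)
        assert fwd_deltas == rev_deltas


class TestClassification:
    CRIT = CriteriaConfig()

    @pytest.mark.parametrize(
        "origin,delta,ri_final,expected",
        [
            # natural-site grid
            (Origin.NATURAL, -10.9, 0.6, Classification.INACTIVATING),
            (Origin.NATURAL, -2.5, 7.5, Classification.LEAKY_WEAKENED),
            (Origin.NATURAL, -0.05, 5.0, Classification.NONE),
            (Origin.NATURAL, -0.05, 1.0, Classification.INACTIVATING),
            (Origin.NATURAL, 0.0, 5.0, Classification.NONE),
            (Origin.NATURAL, 0.05, 5.0, Classification.NONE),
            (Origin.NATURAL, 3.6, 4.0, Classification.STRENGTHENED),
            (Origin.NATURAL, 0.1, 0.5, Classification.STRENGTHENED),
            # cryptic grid (no context flags)
            (Origin.CRYPTIC, 3.6, 4.0, Classification.CRYPTIC_ACTIVATED),
            (Origin.CRYPTIC, 0.5, 1.0, Classification.NONE),
            (Origin.CRYPTIC, -1.0, 5.0, Classification.NONE),
            (Origin.CRYPTIC, 0.0, 5.0, Classification.NONE),
        ],
    )
    def test_truth_table(self, origin, delta, ri_final, expected):
        assert classify_effect(make_effect(origin, delta, ri_final), self.CRIT) == expected

    def test_paper_style_rows(self):
        # abolished natural acceptor
        assert classify_effect(make_effect(Origin.NATURAL, 0.6 - 11.5, 0.6)) \
            == Classification.INACTIVATING
        # leaky natural site
        assert classify_effect(make_effect(Origin.NATURAL, -2.5, 7.5)) \
            == Classification.LEAKY_WEAKENED
        # strengthened cryptic donor
        assert classify_effect(make_effect(Origin.CRYPTIC, 3.6, 4.0)) \
            == Classification.CRYPTIC_ACTIVATED

    def test_unchanged_cryptic_exceeding_weakened_natural_is_activated(self):
        eff = make_effect(Origin.CRYPTIC, 0.0, 11.8, exceeds_natural=True)
        assert classify_effect(eff, self.CRIT) == Classification.CRYPTIC_ACTIVATED

    def test_pseudoexon_needs_deep_intron_and_threshold_crossing(self):
        crossing = make_effect(Origin.CRYPTIC, 2.0, 2.5, deep_intronic=True)
        assert classify_effect(crossing, self.CRIT) == Classification.PSEUDOEXON_CANDIDATE
        shallow = make_effect(Origin.CRYPTIC, 2.0, 2.5, deep_intronic=False)
        assert classify_effect(shallow, self.CRIT) != Classification.PSEUDOEXON_CANDIDATE


class TestCandidateFilter:
    def test_sp_flag_thresholds(self):
        crit = CriteriaConfig()
        flagged = candidate_filter([make_effect(Origin.NATURAL, -1.1, 5.0, het=0.5)], crit)
        assert flagged[0].sp_flagged
        not_flagged = candidate_filter([make_effect(Origin.NATURAL, -0.9, 5.0, het=0.5)], crit)
        assert not not_flagged[0].sp_flagged
        low_het = candidate_filter([make_effect(Origin.NATURAL, -2.0, 5.0, het=0.05)], crit)
        assert not low_het[0].sp_flagged
        no_het = candidate_filter([make_effect(Origin.NATURAL, -2.0, 5.0, het=None)], crit)
        assert no_het[0].sp_flagged  # het test skipped when absent

    def test_random_effects_match_brute_force_predicate(self, rng):
        crit = CriteriaConfig()
        effects = []
        for _ in range(200):
            origin = Origin.NATURAL if rng.random() < 0.7 else Origin.CRYPTIC
            delta = float(rng.normal(0, 2))
            het = float(rng.random()) if rng.random() < 0.8 else None
            comparable = bool(rng.random() < 0.3)
            effects.append(make_effect(origin, delta, float(rng.normal(5, 3)),
                                       het=het, comparable=comparable))
        for flags in candidate_filter(effects, crit):
            e = flags.effect
            sp_expected = (
                e.site.origin == Origin.NATURAL
                and e.delta_ri < -1.0
                and (e.variant.het is None or e.variant.het > 0.10)
            )
            array_expected = abs(e.delta_ri) >= 0.1 or (
                e.site.origin == Origin.CRYPTIC and e.comparable
            )
            assert flags.sp_flagged == sp_expected
            assert flags.array_flagged == array_expected


class TestExonDefinition:
    def test_null_model_is_additive(self):
        score = exon_definition_total(11.4, 9.1, 120)
        assert score.ri_total == pytest.approx(20.5)
        assert score.length_term == 0.0

    def test_modal_length_contributes_zero(self):
        hist = LengthHistogram.from_lengths([100] * 50 + [200] * 10 + [300] * 5)
        assert hist.length_term(100) == pytest.approx(0.0)

    def test_length_term_matches_hand_computation(self):
        hist = LengthHistogram(
            bin_edges=np.array([0.0, 100.0, 200.0, 300.0]),
            counts=np.array([10.0, 40.0, 5.0]),
        )
        # p = [10/55, 40/55, 5/55]; mode is bin 1
        expected = -math.log2(10 / 55) - (-math.log2(40 / 55))
        assert hist.length_term(50) == pytest.approx(expected, abs=1e-12)
        score = exon_definition_total(10.0, 5.0, 50, hist)
        assert score.ri_total == pytest.approx(15.0 - expected, abs=1e-12)

    def test_out_of_support_gets_largest_penalty_with_warning(self):
        hist = LengthHistogram(
            bin_edges=np.array([0.0, 100.0, 200.0]),
            counts=np.array([40.0, 10.0]),
        )
        with pytest.warns(UserWarning, match="largest-bin penalty"):
            term = hist.length_term(5000)
        assert term == pytest.approx(-math.log2(10 / 50) + math.log2(40 / 50))

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            exon_definition_total(float("inf"), 1.0, 10)
        with pytest.raises(ValidationError):
            exon_definition_total(1.0, 1.0, 0)


class TestEffectsTable:
    def test_dataframe_has_full_precision_and_report_columns(self, locus):
        planted = plant_variant(locus, locus.natural_sites[0], target_delta=-2.0)
        effects = evaluate_variant(
            planted.variant, locus.model, locus.genome, locus.matrices
        )
        df = effects_to_dataframe(effects)
        assert {"ri_initial", "ri_final", "delta_ri", "fold",
                "delta_ri_1dp", "fold_1dp", "classification"} <= set(df.columns)
        row = df[df.origin == "natural"].iloc[0]
        assert row["delta_ri_1dp"] == round(row["delta_ri"], 1)
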
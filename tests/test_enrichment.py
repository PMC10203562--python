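"""Variant extraction, clustering and enrichment-factor computation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from displaycamp.amplicon import (
    PARENTAL_DNA_KEY,
    PARENTAL_KEY,
    VariantKey,
    bococizumab_template,
)
from displaycamp.enrichment import (
    EmptySampleError,
    ConfigurationError,
    Rejection,
    SampleCounts,
    cluster_counts,
    count_sample,
    enrichment_factor,
    extract_variant,
    format_ef,
    normalized_counts,
    pair_enrichment,
    residue_enrichment,
    round_trajectory,
)
from displaycamp.library_design import DegenerateLibraryDesign
from displaycamp.synthetic import simulate_library, simulate_reads


@pytest.fixture(scope="module")
def template():
    return bococizumab_template()


def _sample(counts, sample_id="s"):
    return SampleCounts(sample_id=sample_id, counts=counts)


def key(vh, vl, dna=None):
    return VariantKey(vl_pair=vl, vh_pair=vh, dna_key=dna)


class TestVariantKey:
    def test_from_dna_translates(self):
        k = VariantKey.from_dna("GGTCAG" + "CCTTTT")
        assert (k.vl_pair, k.vh_pair) == ("GQ", "PF")

    def test_dna_key_must_translate_to_pairs(self):
        with pytest.raises(ValueError):
            VariantKey(vl_pair="AA", vh_pair="AA", dna_key=PARENTAL_DNA_KEY)

    def test_residue_lookup(self):
        assert PARENTAL_KEY.residue("VL94") == "L"
        assert PARENTAL_KEY.residue("VH54") == "F"

    def test_stop_detection(self):
        assert VariantKey.from_dna("TAGTGGCCTTTT").has_stop


class TestExtractVariant:
    def test_direct_translation(self, template):
        read = template.build("GGTCAG" + PARENTAL_DNA_KEY[6:])
        result = extract_variant(read, template)
        assert isinstance(result, VariantKey)
        assert result.vl_pair == "GQ"
        assert result.vh_pair == "PF"
        assert result.dna_key == "GGTCAG" + PARENTAL_DNA_KEY[6:]

    def test_reverse_complement_read_accepted(self, template):
        from Bio.Seq import reverse_complement

        read = reverse_complement(template.build(PARENTAL_DNA_KEY))
        result = extract_variant(read, template)
        assert result == VariantKey.from_dna(PARENTAL_DNA_KEY)

    def test_two_anchor_mismatches_rejected(self, template):
        read = template.build(PARENTAL_DNA_KEY)
        # mutate two bases inside the 17-nt VL upstream anchor
        corrupted = "TT" + read[2:]
        assert read[:2] != "TT"
        result = extract_variant(corrupted, template, max_anchor_mismatches=1)
        assert result == Rejection("anchor_not_found")

    def test_one_mismatch_tolerated(self, template):
        read = template.build(PARENTAL_DNA_KEY)
        corrupted = ("T" if read[0] != "T" else "A") + read[1:]
        result = extract_variant(corrupted, template, max_anchor_mismatches=1)
        assert isinstance(result, VariantKey)

    def test_truncated_read_rejected(self, template):
        read = template.build(PARENTAL_DNA_KEY)
        result = extract_variant(read[: template.length - 30], template)
        assert result == Rejection("length_mismatch")

    def test_ambiguous_base_in_patch(self, template):
        read = template.build(PARENTAL_DNA_KEY)
        (vl_s, _), _ = template.codon_offsets
        corrupted = read[:vl_s] + "N" + read[vl_s + 1 :]
        assert extract_variant(corrupted, template) == Rejection("ambiguous_base")

    def test_simulator_roundtrip_noiseless(self, template):
        design = DegenerateLibraryDesign.from_pattern("NNK", 4)
        pop = simulate_library(design, n_integrants=500, seed=7)
        reads = simulate_reads(pop, template, depth=2000, per_base_error=0.0, seed=8)
        sample = count_sample(
            (r.sequence for r in reads), template, sample_id="rt", level="dna"
        )
        assert sample.n_rejected == 0
        assert sample.total_reads == 2000
        # recovered composition is exactly the multinomial draw
        assert set(sample.counts) <= set(pop.frequencies)

    def test_accepted_plus_rejected_equals_input(self, template):
        design = DegenerateLibraryDesign.from_pattern("NNK", 4)
        pop = simulate_library(design, n_integrants=200, seed=3)
        reads = simulate_reads(pop, template, depth=1000, per_base_error=0.02, seed=4)
        sample = count_sample((r.sequence for r in reads), template)
        assert sample.total_reads + sample.n_rejected == 1000


class TestClusterCounts:
    def test_synonymous_aggregation(self):
        # GGT and GGG both encode glycine at VL94
        keys = [
            VariantKey.from_dna("GGTCAGCCTTTT"),
            VariantKey.from_dna("GGGCAGCCTTTT"),
        ]
        aa = cluster_counts(keys, level="aa")
        assert aa.counts == {key("PF", "GQ"): 2}
        dna = cluster_counts(keys, level="dna")
        assert len(dna.counts) == 2
        assert all(n == 1 for n in dna.counts.values())

    def test_aa_counts_conserve_dna_counts(self):
        keys = [
            VariantKey.from_dna(d)
            for d in ("GGTCAGCCTTTT", "GGGCAGCCTTTT", "GGTCAGCCGTTT", "CTGTGGCCTTTT")
        ] * 3
        dna = cluster_counts(keys, level="dna")
        aa = cluster_counts(keys, level="aa")
        for aa_key, count in aa.counts.items():
            synonymous = sum(
                n for k, n in dna.counts.items() if k.aa_key == aa_key
            )
            assert synonymous == count

    def test_empty_stream_rejected(self):
        with pytest.raises(EmptySampleError):
            cluster_counts([])


class TestNormalizedCounts:
    def test_final_round_parental_fraction(self):
        sample = _sample({key("PF", "LW"): 80, key("SE", "GQ"): 99_920})
        assert normalized_counts(sample)[key("PF", "LW")] == pytest.approx(0.0008)

    def test_single_variant(self):
        sample = _sample({key("PF", "LW"): 5})
        assert normalized_counts(sample) == {key("PF", "LW"): 1.0}

    def test_uniform_sample(self):
        sample = _sample({key("AA", "AA"): 5, key("CC", "CC"): 5,
                          key("GG", "GG"): 5, key("SS", "SS"): 5})
        assert all(v == 0.25 for v in normalized_counts(sample).values())

    def test_sums_to_one(self):
        sample = _sample({key("PF", "LW"): 123, key("SE", "GQ"): 4567,
                          key("AE", "GQ"): 89})
        assert sum(normalized_counts(sample).values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_sample_error(self):
        with pytest.raises(EmptySampleError):
            normalized_counts(_sample({}))


class TestEnrichmentFactor:
    def test_parental_worked_example(self):
        rec = enrichment_factor(0.013, 0.0008)
        assert rec.enrichment_factor == pytest.approx(0.0615, abs=0.0001)
        assert format_ef(rec.enrichment_factor) == "0.06"
        assert round(rec.de_enrichment_fold) == 16

    def test_no_enrichment(self):
        assert enrichment_factor(0.4, 0.4).enrichment_factor == pytest.approx(1.0)

    def test_zero_pre_is_undefined_not_error(self):
        rec = enrichment_factor(0.0, 0.01)
        assert rec.status == "undefined_pre_zero"
        assert math.isnan(rec.enrichment_factor)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            enrichment_factor(1.3, 0.5)

    @settings(max_examples=50, deadline=None)
    @given(
        counts=st.lists(st.integers(1, 1000), min_size=2, max_size=6),
        scale=st.integers(2, 50),
    )
    def test_scale_invariance(self, counts, scale):
        """Multiplying all counts in a sample by a constant leaves EFs unchanged."""
        variants = [key("AA", "AA"), key("CC", "CC"), key("GG", "GG"),
                    key("SS", "SS"), key("TT", "TT"), key("VV", "VV")][: len(counts)]
        pre = _sample(dict(zip(variants, counts)), "pre")
        final = _sample(dict(zip(variants, reversed(counts))), "fin")
        scaled = _sample({k: n * scale for k, n in final.counts.items()}, "fin2")
        nc_pre = normalized_counts(pre)
        for v in variants:
            a = enrichment_factor(nc_pre[v], normalized_counts(final)[v])
            b = enrichment_factor(nc_pre[v], normalized_counts(scaled)[v])
            assert a.enrichment_factor == pytest.approx(b.enrichment_factor)


class TestResidueEnrichment:
    def test_hand_computed_marginals(self):
        pre = _sample({key("PF", "LW"): 50, key("PE", "LW"): 50}, "pre")
        final = _sample({key("PF", "LW"): 10, key("PE", "LW"): 90}, "fin")
        table = residue_enrichment(pre, final, "VH54")
        assert table.enrichment["F"].enrichment_factor == pytest.approx(0.2)
        assert table.enrichment["E"].enrichment_factor == pytest.approx(1.8)
        assert table.enrichment["F"].de_enrichment_fold == pytest.approx(5.0)

    def test_identical_samples_give_unit_ef(self):
        counts = {key("PF", "LW"): 30, key("SE", "GQ"): 70}
        table = residue_enrichment(_sample(counts, "pre"), _sample(counts, "fin"), "VL95")
        assert all(
            r.enrichment_factor == pytest.approx(1.0)
            for r in table.enrichment.values()
        )

    def test_residue_absent_from_final(self):
        pre = _sample({key("PF", "LW"): 50, key("PE", "LW"): 50}, "pre")
        final = _sample({key("PE", "LW"): 100}, "fin")
        table = residue_enrichment(pre, final, "VH54")
        assert table.enrichment["F"].enrichment_factor == 0.0

    def test_marginals_consistent_with_joint_counts(self):
        counts = {key("PF", "LW"): 5, key("PE", "LW"): 7, key("SE", "GQ"): 11}
        sample = _sample(counts, "s")
        table = residue_enrichment(sample, sample, "VH53")
        total = sample.total_reads
        for res, freq in table.frequencies["s"].items():
            joint = sum(n for k, n in counts.items() if k.residue("VH53") == res)
            assert freq == pytest.approx(joint / total)

    def test_frequencies_sum_to_one(self):
        counts = {key("PF", "LW"): 5, key("PE", "GQ"): 7, key("SE", "GQ"): 11}
        table = residue_enrichment(_sample(counts, "pre"), _sample(counts, "fin"), "VL94")
        assert sum(table.frequencies["pre"].values()) == pytest.approx(1.0)

    def test_unknown_position(self):
        sample = _sample({key("PF", "LW"): 1})
        with pytest.raises(ConfigurationError):
            residue_enrichment(sample, sample, "VH99")


class TestPairEnrichment:
    def test_single_variant_combined(self):
        pre = _sample({key("PF", "LW", PARENTAL_DNA_KEY): 10}, "pre")
        final = _sample({key("PF", "LW", PARENTAL_DNA_KEY): 20}, "fin")
        records = pair_enrichment(pre, final, "combined")
        assert len(records) == 1
        assert records[0].status == "defined"
        assert records[0].enrichment_factor == pytest.approx(1.0)

    def test_multiplicative_toy_joint(self):
        # counts chosen multiplicative: joint EF = product of marginal EFs
        pre = _sample(
            {key("PF", "LW"): 40, key("PF", "GQ"): 40,
             key("SE", "LW"): 10, key("SE", "GQ"): 10},
            "pre",
        )
        final = _sample(
            {key("PF", "LW"): 10, key("PF", "GQ"): 10,
             key("SE", "LW"): 40, key("SE", "GQ"): 40},
            "fin",
        )
        joint = {str(r.variant): r.enrichment_factor
                 for r in pair_enrichment(pre, final, "combined")}
        vh = {r.variant: r.enrichment_factor
              for r in pair_enrichment(pre, final, "vh")}
        vl = {r.variant: r.enrichment_factor
              for r in pair_enrichment(pre, final, "vl")}
        for vh_pair in ("PF", "SE"):
            for vl_pair in ("LW", "GQ"):
                assert joint[f"{vh_pair}/{vl_pair}"] == pytest.approx(
                    vh[vh_pair] * vl[vl_pair]
                )

    def test_sorted_descending_with_top(self):
        pre = _sample({key("PF", "LW"): 50, key("SE", "GQ"): 25, key("AE", "GQ"): 25}, "p")
        final = _sample({key("PF", "LW"): 5, key("SE", "GQ"): 80, key("AE", "GQ"): 15}, "f")
        records = pair_enrichment(pre, final, "combined", top=2)
        assert len(records) == 2
        assert str(records[0].variant) == "SE/GQ"
        assert records[0].enrichment_factor >= records[1].enrichment_factor

    def test_stop_variants_excluded_by_default(self):
        pre = _sample({key("PF", "LW"): 50, key("P*", "LW"): 50}, "p")
        final = _sample({key("PF", "LW"): 90, key("P*", "LW"): 10}, "f")
        default = pair_enrichment(pre, final, "combined")
        assert all("*" not in str(r.variant) for r in default)
        included = pair_enrichment(pre, final, "combined", include_stops=True)
        assert len(included) == len(default) + 1
        # stop reads stay in the denominator either way
        assert default[0].nc_sample == pytest.approx(0.9)


class TestRoundTrajectory:
    def test_requires_pre_selection(self):
        sample = _sample({key("PF", "LW"): 1}, "pre-selection")
        with pytest.raises(ConfigurationError):
            round_trajectory({"pre-selection": sample})

    def test_missing_pre_sample(self):
        sample = _sample({key("PF", "LW"): 1}, "r1")
        with pytest.raises(ConfigurationError):
            round_trajectory({"r1": sample})

    def test_two_round_hand_computation(self):
        pre = _sample({key("PF", "LW"): 80, key("SE", "GQ"): 20}, "pre-selection")
        r1 = _sample({key("PF", "LW"): 50, key("SE", "GQ"): 50}, "r1")
        r2 = _sample({key("PF", "LW"): 20, key("SE", "GQ"): 80}, "r2")
        traj = round_trajectory({"pre-selection": pre, "r1": r1, "r2": r2})
        assert traj.loc["PF/LW", "r1"] == pytest.approx(0.5 / 0.8)
        assert traj.loc["SE/GQ", "r2"] == pytest.approx(0.8 / 0.2)

    def test_all_equal_rounds_give_unit_ef(self):
        counts = {key("PF", "LW"): 30, key("SE", "GQ"): 70}
        traj = round_trajectory(
            {"pre-selection": _sample(counts, "pre-selection"),
             "r1": _sample(counts, "r1"), "r2": _sample(counts, "r2")}
        )
        assert (traj.to_numpy() == pytest.approx(1.0)) or (
            abs(traj.to_numpy() - 1.0) < 1e-12
        ).all()
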
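import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from pdxtrial import (AnnotatedVariant, CallerThresholds, PileupColumn,
                      VariantCall, apply_whitelist, call_pileup,
                      end_of_read_only, evaluate_variants, filter_cascade,
                      flag_confidence, homopolymer_adjacent, merge_callsets,
                      mutation_prevalence, oncoprint, read_vcf, write_vcf)
from pdxtrial.synthetic import (VariantSimSpec, gen_hotspot_cohort,
                                gen_variants, variants_from_sim)
from pdxtrial.variants import (CASCADE_RULES, CELL_HIGH, CELL_LOW, CELL_NONE,
                               RETAINED, RULE_DBSNP)


def _column(ref="A", obs=()):
    return PileupColumn("chr1", 100, ref, tuple(obs))


class TestCallPileup:
    def test_minimum_coverage(self):
        # a single high-quality alt read is below min-coverage 2
        calls = call_pileup([_column(obs=[("T", 30.0)])])
        assert calls == []

    def test_all_thresholds_at_minima(self):
        calls = call_pileup([_column(obs=[("T", 20.0), ("T", 20.0)])])
        assert len(calls) == 1
        c = calls[0]
        assert (c.vaf, c.avg_alt_quality, c.depth, c.alt_reads) == (1.0, 20.0, 2, 2)

    def test_vaf_boundary_inclusive(self):
        # 2 alt reads in depth 200 is VAF exactly 0.01 -> call;
        # depth 201 puts it below the threshold -> no call
        ref_obs = [("A", 30.0)] * 198
        alt_obs = [("T", 20.0), ("T", 20.0)]
        assert len(call_pileup([_column(obs=ref_obs + alt_obs)])) == 1
        assert call_pileup([_column(obs=ref_obs + [("A", 30.0)] + alt_obs)]) == []

    def test_degenerate_thresholds_emit_all_nonref_bases(self):
        # with thresholds (1,1,0,0) the call set is exactly each column's
        # non-reference base set
        rng = np.random.default_rng(0)
        loose = CallerThresholds(1, 1, 0.0, 0.0)
        for _ in range(30):
            bases = rng.choice(list("ACGT"), size=rng.integers(1, 8))
            col = PileupColumn("chr1", 50, "A",
                               tuple((b, float(rng.integers(1, 40)))
                                     for b in bases))
            called = {c.alt for c in call_pileup([col], loose)}
            assert called == set(bases) - {"A"}

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            _column(obs=[("N", 30.0)])

    def test_exhaustive_boundary_grid(self):
        """Calls appear exactly when all four inclusive thresholds hold."""
        thresholds = CallerThresholds()
        for n_ref in range(0, 4):
            for n_alt in range(0, 4):
                if n_ref + n_alt == 0:
                    continue
                for qual in (14.0, 14.999, 15.0, 16.0):
                    obs = [("A", 30.0)] * n_ref + [("T", qual)] * n_alt
                    depth = n_ref + n_alt
                    expected = (depth >= 2 and n_alt >= 2
                                and n_alt / depth >= 0.01 and qual >= 15.0)
                    got = call_pileup([_column(obs=obs)], thresholds)
                    assert bool(got) == expected, (n_ref, n_alt, qual)


class TestMergeCallsets:
    def _call(self, sample="s1", pos=5, alt_reads=3, source="per_sample"):
        return VariantCall("chr1", pos, "A", "T", 50, alt_reads,
                           alt_reads / 50, 30.0, sample, source)

    def test_disjoint_concatenation(self):
        a, b = self._call(sample="s1"), self._call(sample="s2")
        assert len(merge_callsets([[a], [b]])) == 2

    def test_identical_duplicate_collapses(self):
        a = self._call()
        assert len(merge_callsets([[a], [a]])) == 1

    def test_collision_keeps_higher_support(self):
        a = self._call(alt_reads=3)
        b = self._call(alt_reads=5, source="pooled")
        merged = merge_callsets([[a]], [b])
        assert len(merged) == 1
        assert merged[0].alt_reads == 5 and merged[0].source == "pooled"

    def test_conflicting_ref_rejected(self):
        a = self._call()
        b = VariantCall("chr1", 5, "G", "T", 50, 3, 0.06, 30.0, "s2")
        with pytest.raises(ValueError):
            merge_callsets([[a], [b]])

    def test_idempotent_and_order_insensitive(self):
        rng = np.random.default_rng(1)
        calls = [self._call(sample=f"s{rng.integers(3)}",
                            pos=int(rng.integers(1, 5)),
                            alt_reads=int(rng.integers(2, 30)))
                 for _ in range(20)]
        merged = merge_callsets([calls])
        assert merge_callsets([merged]) == merged
        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert merge_callsets([shuffled]) == merged


def _annotated(**overrides):
    base = dict(chrom="chr7", pos=140453136, ref="A", alt="T", depth=60,
                alt_reads=20, vaf=1 / 3, avg_alt_quality=32.0,
                sample_id="s1", source="per_sample", gene="BRAF",
                region="exonic", consequence="missense",
                dbsnp_status="absent", in_cosmic=True, gene_role="oncogene",
                in_esp6500=False, in_1000g=False,
                homopolymer_adjacent=False, end_of_read_only=False)
    base.update(overrides)
    return AnnotatedVariant(**base)


class TestFilterCascade:
    def test_cosmic_oncogene_retained(self):
        assert filter_cascade(_annotated()) == RETAINED

    def test_clean_novel_tumor_suppressor_retained(self):
        v = _annotated(gene="NF1", gene_role="tumor_suppressor",
                       in_cosmic=False, consequence="nonsense")
        assert filter_cascade(v) == RETAINED

    def test_nonflagged_dbsnp_discarded(self):
        assert filter_cascade(_annotated(dbsnp_status="nonflagged")) == RULE_DBSNP

    @pytest.mark.parametrize("overrides,rule", [
        (dict(region="intronic"), "discarded:region"),
        (dict(consequence="synonymous"), "discarded:synonymous"),
        (dict(dbsnp_status="nonflagged"), "discarded:dbsnp"),
        (dict(in_cosmic=False), "discarded:oncogene_non_cosmic"),
        (dict(gene_role="tumor_suppressor", in_cosmic=False, in_1000g=True),
         "discarded:population_db"),
        (dict(gene_role="other"), "discarded:gene_role"),
        (dict(gene_role="tumor_suppressor", in_cosmic=False,
              homopolymer_adjacent=True), "discarded:homopolymer"),
        (dict(gene_role="tumor_suppressor", in_cosmic=False,
              end_of_read_only=True), "discarded:read_end"),
    ])
    def test_first_failing_rule_named(self, overrides, rule):
        assert filter_cascade(_annotated(**overrides)) == rule

    def test_cosmic_tsg_immune_to_context_filters(self):
        v = _annotated(gene="TP53", gene_role="tumor_suppressor",
                       in_cosmic=True, homopolymer_adjacent=True,
                       end_of_read_only=True, in_1000g=True)
        assert filter_cascade(v) == RETAINED

    def test_missing_annotation_rejected(self):
        v = _annotated(region=None)
        with pytest.raises(ValueError, match="region"):
            filter_cascade(v)

    def test_generator_truth_recovered_for_every_rule(self, variant_table):
        variants = variants_from_sim(variant_table)
        verdicts = [filter_cascade(v) for v in variants]
        assert verdicts == list(variant_table.truth_verdict)
        assert set(variant_table.truth_verdict) == set(CASCADE_RULES) | {RETAINED}

    def test_order_independence(self, variant_table):
        variants = variants_from_sim(variant_table)
        expected = {v.sample_id: filter_cascade(v) for v in variants}
        rng = np.random.default_rng(3)
        for _ in range(5):
            shuffled = list(variants)
            rng.shuffle(shuffled)
            assert {v.sample_id: filter_cascade(v) for v in shuffled} == expected

    def test_all_pass_spec_retains_everything(self):
        table = gen_variants(VariantSimSpec(
            n_retained=6, n_fail_per_rule={}, seed=1))
        assert (table.truth_verdict == RETAINED).all()
        assert all(filter_cascade(v) == RETAINED
                   for v in variants_from_sim(table))

    def test_empty_spec_empty_table(self):
        table = gen_variants(VariantSimSpec(n_retained=0,
                                            n_fail_per_rule={}, seed=1))
        assert table.empty


class TestConfidence:
    @pytest.mark.parametrize("alt_reads,source,expected", [
        (1, "per_sample", "low"),
        (2, "per_sample", "low"),
        (50, "per_sample", "high"),
        (3, "manual", "low"),
    ])
    def test_rule(self, alt_reads, source, expected):
        v = _annotated(alt_reads=alt_reads, source=source)
        assert flag_confidence(v) == expected

    def test_whitelist_rescue(self):
        v = _annotated(dbsnp_status="nonflagged", alt_reads=2)
        out = apply_whitelist(evaluate_variants([v]),
                              [("s1", "chr7", 140453136, "A", "T")])
        assert out[0].verdict == RETAINED
        assert out[0].confidence == "low" and out[0].source == "manual"


class TestHomopolymer:
    def test_adjacent_run_detected(self):
        # variant immediately 5' of an A5 run
        assert homopolymer_adjacent("ACGTAAAAAG", 3)

    def test_short_runs_ignored(self):
        assert not homopolymer_adjacent("ACGTAAAGTC", 3)

    def test_variant_inside_run(self):
        assert homopolymer_adjacent("ACAAAAAAGT", 5)

    def test_distance_beyond_adjacency(self):
        assert not homopolymer_adjacent("ACGTGAAAAAG", 2, adjacency=1)
        assert homopolymer_adjacent("ACGTGAAAAAG", 3, adjacency=2)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            homopolymer_adjacent("ACG", 1)

    def test_end_of_read_only(self):
        assert end_of_read_only([(2, 80), (90, 3)])
        assert not end_of_read_only([(2, 80), (40, 50)])


class TestOncoprint:
    def test_empty_variant_set(self):
        groups = {"s1": "progression", "s2": "regression"}
        mat = oncoprint([], ["s1", "s2"], ["BRAF"], groups)
        assert (mat.values == CELL_NONE).all()

    def test_high_conf_wins_collapse(self):
        groups = {"s1": "progression"}
        high = evaluate_variants([_annotated(alt_reads=30)])[0]
        low = evaluate_variants([_annotated(alt_reads=1)])[0]
        mat = oncoprint([high, low], ["s1"], ["BRAF"], groups)
        assert mat.at["BRAF", "s1"] == CELL_HIGH
        mat = oncoprint([low], ["s1"], ["BRAF"], groups)
        assert mat.at["BRAF", "s1"] == CELL_LOW

    def test_columns_ordered_by_response_group(self):
        groups = {"s1": "regression", "s2": "progression", "s3": "suppression"}
        mat = oncoprint([], ["s1", "s2", "s3"], ["BRAF"], groups)
        assert list(mat.columns) == ["s2", "s3", "s1"]

    def test_unlabeled_sample_rejected(self):
        with pytest.raises(ValueError):
            oncoprint([], ["s1"], ["BRAF"], {})

    def test_cohort_prevalence(self):
        variants, groups = gen_hotspot_cohort(n_samples=31, n_braf=20,
                                              n_nras=11, seed=0)
        mat = oncoprint(variants, list(groups), ["BRAF", "NRAS"], groups)
        assert int((mat.loc["BRAF"] != CELL_NONE).sum()) == 20
        assert int((mat.loc["NRAS"] != CELL_NONE).sum()) == 11
        assert mutation_prevalence(mat) == {"BRAF": 65, "NRAS": 35}


class TestVariantIO:
    def test_vcf_round_trip(self, tmp_path, variant_table):
        variants = evaluate_variants(variants_from_sim(variant_table))
        path = str(tmp_path / "variants.vcf")
        write_vcf(variants, path)
        back = read_vcf(path)
        key = lambda v: (v.chrom, v.pos, v.alt, v.sample_id)
        for orig, rt in zip(sorted(variants, key=key), sorted(back, key=key)):
            od, rd = dataclasses.asdict(orig), dataclasses.asdict(rt)
            assert od.keys() == rd.keys()
            for k in od:
                if isinstance(od[k], float):
                    assert rd[k] == pytest.approx(od[k], rel=1e-5), k
                else:
                    assert rd[k] == od[k], k
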
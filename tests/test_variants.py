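"""Variant filtering rules, background removal, classification, SV calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phageres.synthetic import SimulationConfig, simulate_coverage_track
from phageres.variants import (
    Category,
    GeneCategoryTable,
    VariantRecord,
    call_svs,
    classify_and_count,
    flag_ancestral_background,
    packaged_gene_categories,
    quality_filter,
    read_vcf,
    remove_shared_variants,
    write_vcf,
)

from conftest import make_params


def rec(lineage="L1", pos=100, depth=50, alt=50, ref="A", alt_base="T", gene=None):
    return VariantRecord(lineage, "chr", pos, ref, alt_base, depth, alt, gene=gene)


class TestQualityFilter:
    @pytest.mark.parametrize(
        "depth,alt,kept",
        [
            (25, 21, True),   # 84% of 25 reads
            (20, 20, False),  # depth boundary: 20 is not > 20
            (100, 80, False), # fraction boundary: 0.80 is not > 0.80
            (21, 17, True),   # 17/21 = 0.8095 just clears both strict cuts
        ],
    )
    def test_strict_boundaries(self, depth, alt, kept):
        out = quality_filter([rec(depth=depth, alt=alt)])
        assert bool(out) is kept

    @settings(max_examples=30, derandomize=True)
    @given(
        records=st.lists(
            st.tuples(st.integers(1, 60), st.floats(0.0, 1.0)), max_size=200
        )
    )
    def test_matches_brute_force_predicate(self, records):
        table = [
            rec(pos=i + 1, depth=d, alt=min(int(round(f * d)), d))
            for i, (d, f) in enumerate(records)
        ]
        oracle = [
            r for r in table if r.depth > 20 and r.alt_count / r.depth > 0.8
        ]
        assert quality_filter(table) == oracle


class TestSharedVariants:
    def test_universal_variant_removed_everywhere(self):
        records = [rec(lineage=f"L{i}", pos=500) for i in range(4)] + [
            rec(lineage="L0", pos=900)
        ]
        kept, discarded = remove_shared_variants(records)
        assert discarded == {("chr", 500, "A", "T")}
        assert {r.pos for r in kept} == {900}

    def test_near_universal_variant_retained(self):
        records = [rec(lineage=f"L{i}", pos=500) for i in range(3)]
        records.append(rec(lineage="L3", pos=700))
        kept, discarded = remove_shared_variants(records)
        assert not discarded and len(kept) == 4

    def test_two_lineage_degenerate_case(self):
        # set-intersection oracle applies even at N=2
        records = [rec(lineage="L0", pos=42), rec(lineage="L1", pos=42)]
        kept, discarded = remove_shared_variants(records)
        assert discarded == {("chr", 42, "A", "T")} and kept == []

    def test_requires_two_lineages(self):
        with pytest.raises(ValueError):
            remove_shared_variants([rec()])


class TestAncestralBackground:
    PED = {"FT3a": "FT3", "FT3b": "FT3", "FT3c": "FT3", "FT1a": "FT1", "FT1b": "FT1"}

    def test_universal_within_one_ancestor_flagged(self):
        records = [rec(lineage=l, pos=777) for l in ("FT3a", "FT3b", "FT3c")]
        records += [rec(lineage="FT1a", pos=50), rec(lineage="FT1b", pos=60)]
        out = flag_ancestral_background(records, self.PED)
        flags = {r.lineage: r.background for r in out if r.pos == 777}
        assert all(flags.values()) and len(flags) == 3
        assert not any(r.background for r in out if r.pos != 777)

    def test_partial_within_ancestor_not_flagged(self):
        records = [rec(lineage=l, pos=777) for l in ("FT3a", "FT3b")]
        records += [rec(lineage="FT3c", pos=1), rec(lineage="FT1a", pos=2),
                    rec(lineage="FT1b", pos=3)]
        out = flag_ancestral_background(records, self.PED)
        assert not any(r.background for r in out)

    def test_variant_spanning_two_ancestors_not_flagged(self):
        records = [
            rec(lineage=l, pos=777)
            for l in ("FT3a", "FT3b", "FT3c", "FT1a", "FT1b")
        ]
        out = flag_ancestral_background(records, self.PED)
        assert not any(r.background for r in out)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_order_safe_with_shared_removal(self, seed):
        """Shared-removal and background-flagging commute on random tables."""
        rng = np.random.default_rng(seed)
        lineages = list(self.PED)
        records = []
        for lin in lineages:  # universal artifact
            records.append(rec(lineage=lin, pos=10))
        for lin in ("FT3a", "FT3b", "FT3c"):  # per-ancestor background
            records.append(rec(lineage=lin, pos=20))
        for lin in lineages:  # random private variants
            for _ in range(rng.integers(0, 4)):
                records.append(rec(lineage=lin, pos=int(rng.integers(100, 120))))

        def final_keys(recs):
            return {
                (r.lineage, r.key)
                for r in recs
                if not r.background
            }

        a, _ = remove_shared_variants(records)
        a = flag_ancestral_background(a, self.PED)
        b = flag_ancestral_background(records, self.PED)
        b_kept, _ = remove_shared_variants(b)
        assert final_keys(a) == final_keys(b_kept)


class TestClassification:
    def test_receptor_gene_lookup(self):
        table = packaged_gene_categories()
        assert table.classify("wzy") is Category.LPS
        assert table.classify("pilB") is Category.TYPE_IV_PILUS
        assert table.classify("PA0429") is Category.UNKNOWN
        assert table.classify("ssb") is Category.OTHER
        assert table.classify("not_a_gene") is Category.UNKNOWN

    def test_counts_exclude_background(self):
        records = [
            rec(lineage="L1", pos=1, gene="wzy"),
            rec(lineage="L1", pos=2, gene="pilB"),
            rec(lineage="L2", pos=3, gene="galU"),
        ]
        from dataclasses import replace

        records = [replace(r, background=(r.pos == 2)) for r in records]
        annotated, counts = classify_and_count(records, packaged_gene_categories())
        counts = counts.set_index("lineage")
        assert counts.loc["L1", "total"] == 1  # pilB flagged background
        assert counts.loc["L1", "LPS"] == 1
        assert counts.loc["L2", "total"] == 1
        assert {r.category for r in annotated if r.pos == 2} == {Category.TYPE_IV_PILUS}

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene\tcategory\nwzy\tLPS\nwzy\tOTHER\n")
        with pytest.raises(ValueError, match="wzy"):
            GeneCategoryTable.from_tsv(p)


def uniform_track(n_bins=5000, depth=50, bin_bp=100, seed=0):
    rng = np.random.default_rng(seed)
    starts = np.arange(n_bins) * bin_bp
    return pd.DataFrame(
        {
            "chrom": "c",
            "start": starts,
            "end": starts + bin_bp,
            "depth": rng.poisson(depth, n_bins),
        }
    )


class TestSVCalling:
    def test_uniform_track_has_no_calls(self):
        assert call_svs(uniform_track(), 500_000) == []

    def test_planted_250kb_deletion_on_full_genome(self):
        cfg = SimulationConfig(seed=13)
        params = make_params(sv_events=[("deletion", 1_000_000, 250_000)])
        track = simulate_coverage_track(params, cfg)
        calls = call_svs(track, cfg.genome_length_bp)
        assert len(calls) == 1
        call = calls[0]
        assert call.type == "DELETION"
        assert abs(call.start - 1_000_000) <= cfg.bin_bp
        assert abs(call.end - 1_250_000) <= cfg.bin_bp
        # around 4% of the 6,264,404 bp genome
        assert call.fraction_of_genome == pytest.approx(3.99, abs=0.05)
        assert round(call.fraction_of_genome) == 4

    def test_duplication_recovered_within_one_bin(self):
        hits = 0
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, genome_length_bp=400_000, mean_depth=30)
            params = make_params(sv_events=[("duplication", 200_000, 5_000)])
            track = simulate_coverage_track(params, cfg)
            calls = [
                c for c in call_svs(track, cfg.genome_length_bp)
                if c.type == "DUPLICATION"
            ]
            if (
                len(calls) == 1
                and abs(calls[0].start - 200_000) <= cfg.bin_bp
                and abs(calls[0].end - 205_000) <= cfg.bin_bp
            ):
                hits += 1
        assert hits == 100

    def test_short_deletion_dropped(self):
        track = uniform_track()
        track.loc[10, "depth"] = 0  # single 100 bp bin: not > 100 bp... exactly 100
        calls = call_svs(track, 500_000, min_deletion_bp=200)
        assert calls == []

    def test_zero_median_track_rejected(self):
        track = uniform_track()
        track["depth"] = 0
        with pytest.raises(ValueError, match="median"):
            call_svs(track, 500_000)


class TestVcfRoundTrip:
    def test_write_then_read_preserves_records(self, tmp_path):
        records = [
            rec(lineage="LX", pos=100, depth=42, alt=40, gene="wzy"),
            rec(lineage="LX", pos=5000, depth=33, alt=30),
        ]
        path = tmp_path / "LX.vcf"
        write_vcf(records, path, "chr", 100_000)
        back = read_vcf(path, "LX")
        assert [(r.pos, r.depth, r.alt_count, r.gene) for r in back] == [
            (100, 42, 40, "wzy"),
            (5000, 33, 30, None),
        ]
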
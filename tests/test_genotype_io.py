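import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedtrace.genotype_io import (
    EmptyCohortError,
    FilterConfig,
    MISSING,
    UndefinedRateError,
    apply_site_filters,
    filter_individuals,
    ld_thin,
    read_vcf,
    replicate_error_rates,
    write_vcf,
)
from seedtrace.simulate import simulate_genotypes

from conftest import make_matrix


class TestVcfRoundTrip:
    def test_basic_read(self, tmp_path):
        text = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1
chr1\t20\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t1/1
chr1\t30\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\t./.
"""
        p = tmp_path / "t.vcf"
        p.write_text(text)
        G = read_vcf(p)
        assert G.individual_ids == ["s1", "s2"]
        assert G.dosages.tolist() == [[0, 1, 2], [1, 2, MISSING]]

    def test_multiallelic_excluded(self, tmp_path):
        text = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
chr1\t10\t.\tA\tT,C\t.\tPASS\t.\tGT\t0/1
chr1\t20\t.\tG\tC\t.\tPASS\t.\tGT\t0/1
"""
        p = tmp_path / "t.vcf"
        p.write_text(text)
        G = read_vcf(p)
        assert G.n_loci == 1
        assert G.n_excluded_records == 1

    def test_round_trip_simulated(self, tmp_path, rng):
        Q = rng.dirichlet(np.ones(2), size=12)
        P = rng.uniform(0.05, 0.95, size=(2, 300))
        G = simulate_genotypes(Q, P, 0.1, rng)
        path = write_vcf(G, tmp_path / "sim.vcf")
        H = read_vcf(path)
        assert np.array_equal(G.dosages, H.dosages)
        assert np.array_equal(G.positions, H.positions)
        assert list(G.scaffolds) == list(H.scaffolds)
        assert G.individual_ids == H.individual_ids
        assert np.array_equal(G.genotype_depth, H.genotype_depth)

    def test_empty_matrix(self, tmp_path):
        G = make_matrix(np.empty((2, 0), dtype=np.int8))
        path = write_vcf(G, tmp_path / "empty.vcf")
        H = read_vcf(path)
        assert H.n_loci == 0
        assert H.individual_ids == ["s0", "s1"]

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_property(self, seed):
        import tempfile, os

        rng = np.random.default_rng(seed)
        n, j = int(rng.integers(1, 6)), int(rng.integers(1, 40))
        d = rng.integers(0, 4, size=(n, j)).astype(np.int8)
        d[d == 3] = MISSING
        pos = np.sort(rng.choice(np.arange(1, 10_000), size=j, replace=False))
        G = make_matrix(d, positions=pos)
        with tempfile.TemporaryDirectory() as tmp:
            path = write_vcf(G, os.path.join(tmp, "x.vcf"))
            H = read_vcf(path)
        assert np.array_equal(G.dosages, H.dosages)
        assert np.array_equal(G.positions, H.positions)


def _brute_force_cascade(G, cfg):
    """Independent site-filter oracle: exhaustive per-site scan."""
    d = G.dosages.copy()
    if G.genotype_depth is not None:
        d[(G.genotype_depth < cfg.min_genotype_depth) & (d != MISSING)] = MISSING
    keep = []
    for j in range(d.shape[1]):
        col = d[:, j]
        called = col[col != MISSING]
        alt = int(called.sum())
        total = 2 * len(called)
        mac = min(alt, total - alt)
        if mac < cfg.min_minor_allele_count:
            continue
        dp = G.site_annotations["MEAN_DP"][j]
        if dp < cfg.min_mean_site_depth or dp > cfg.max_mean_site_depth:
            continue
        ab = G.site_annotations["AB"][j]
        if ab > 0 and (ab <= cfg.het_allele_balance[0] or ab >= cfg.het_allele_balance[1]):
            continue
        mqr = G.site_annotations["MQR"][j]
        if not (cfg.mapq_ratio[0] < mqr < cfg.mapq_ratio[1]):
            continue
        qd = G.site_annotations["QD"][j]
        if not qd > cfg.min_quality_per_depth:
            continue
        if np.mean(col == MISSING) > cfg.max_site_missingness:
            continue
        keep.append(j)
    return keep


class TestSiteFilters:
    def test_monomorphic_removed(self):
        G = make_matrix([[0, 1], [0, 1]])
        out, report = apply_site_filters(G, FilterConfig())
        assert out.n_loci == 1
        assert dict(report)["minor_allele_count"] == 1

    def test_missingness_threshold(self):
        d = np.ones((10, 1), dtype=np.int8)
        d[:2, 0] = MISSING  # 20% > 10%
        G = make_matrix(d)
        # disable MAC so only missingness acts
        out, report = apply_site_filters(
            G, FilterConfig(min_minor_allele_count=0, min_genotype_depth=0)
        )
        assert out.n_loci == 0
        assert dict(report)["site_missingness"] == 1

    def test_cascade_matches_brute_force(self, rng):
        n, j = 20, 200
        d = rng.integers(0, 3, size=(n, j)).astype(np.int8)
        d[rng.random((n, j)) < 0.1] = MISSING
        ann = {
            "MEAN_DP": rng.uniform(1, 40, j),
            "AB": rng.uniform(0.0, 1.0, j),
            "QD": rng.uniform(0.0, 2.0, j),
            "MQR": rng.uniform(0.0, 2.5, j),
        }
        depth = rng.integers(0, 20, size=(n, j)).astype(np.int32)
        G = make_matrix(d, annotations=ann, genotype_depth=depth)
        cfg = FilterConfig()
        out, _ = apply_site_filters(G, cfg)
        expected = _brute_force_cascade(G, cfg)
        assert out.positions.tolist() == G.positions[expected].tolist()

    def test_idempotent(self, rng):
        n, j = 15, 120
        d = rng.integers(0, 3, size=(n, j)).astype(np.int8)
        d[rng.random((n, j)) < 0.15] = MISSING
        ann = {
            "MEAN_DP": rng.uniform(1, 40, j),
            "AB": rng.uniform(0.0, 1.0, j),
            "QD": rng.uniform(0.0, 2.0, j),
            "MQR": rng.uniform(0.0, 2.5, j),
        }
        G = make_matrix(d, annotations=ann)
        cfg = FilterConfig()
        once, _ = apply_site_filters(G, cfg)
        twice, report = apply_site_filters(once, cfg)
        assert np.array_equal(once.dosages, twice.dosages)
        assert all(removed == 0 for _, removed in report)

    def test_missing_annotation_skipped(self, recwarn):
        G = make_matrix([[0, 1], [1, 1]])
        out, _ = apply_site_filters(G, FilterConfig())
        assert any("skipped" in str(w.message) for w in recwarn.list)
        assert out.n_loci >= 1


class TestFilterIndividuals:
    def test_over_threshold_removed(self):
        d = np.zeros((2, 100), dtype=np.int8)
        d[0, 1::2] = 1
        d[1, :56] = MISSING  # 56% missing
        G = make_matrix(d)
        out = filter_individuals(G, 0.55)
        assert out.individual_ids == ["s0"]

    def test_exactly_at_threshold_retained(self):
        d = np.zeros((2, 100), dtype=np.int8)
        d[0, 1::2] = 1
        d[1, :55] = MISSING  # exactly 55%: "more than" -> keep
        G = make_matrix(d)
        out = filter_individuals(G, 0.55)
        assert out.individual_ids == ["s0", "s1"]

    def test_fully_observed_unchanged(self):
        G = make_matrix([[0, 1], [2, 1]])
        out = filter_individuals(G, 0.55)
        assert out is G

    def test_empty_cohort_error(self):
        d = np.full((2, 10), MISSING, dtype=np.int8)
        with pytest.raises(EmptyCohortError):
            filter_individuals(make_matrix(d), 0.5)


def _greedy_thin_oracle(scaffolds, positions, window):
    kept = []
    last = {}
    for j, (s, p) in enumerate(zip(scaffolds, positions)):
        if s not in last or p - last[s] >= window:
            kept.append(j)
            last[s] = p
    return kept


class TestLdThin:
    def test_boundary(self):
        G = make_matrix(np.zeros((1, 3), dtype=np.int8), positions=[1, 4999, 5001])
        out = ld_thin(G, 5000)
        assert out.positions.tolist() == [1, 5001]

    def test_two_scaffolds_independent(self):
        G = make_matrix(
            np.zeros((1, 6), dtype=np.int8),
            positions=[1, 4999, 5001, 1, 4999, 5001],
            scaffolds=["c1"] * 3 + ["c2"] * 3,
        )
        out = ld_thin(G, 5000)
        assert out.positions.tolist() == [1, 5001, 1, 5001]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_and_min_gap(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(2, 400))
        pos = np.sort(rng.choice(np.arange(1, 100_000), size=j, replace=False))
        G = make_matrix(np.zeros((1, j), dtype=np.int8), positions=pos)
        out = ld_thin(G, 5000)
        oracle = _greedy_thin_oracle(G.scaffolds, G.positions, 5000)
        assert out.positions.tolist() == G.positions[oracle].tolist()
        assert np.all(np.diff(out.positions) >= 5000)

    def test_unsorted_input_sorted_first(self):
        G = make_matrix(np.zeros((1, 3), dtype=np.int8), positions=[5001, 1, 4999])
        out = ld_thin(G, 5000)
        assert out.positions.tolist() == [1, 5001]


class TestReplicateErrorRates:
    def test_identical(self):
        a = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        r = replicate_error_rates([(a, a.copy())])
        assert (r.global_rate, r.homozygous, r.heterozygous) == (0.0, 0.0, 0.0)

    def test_single_discordance(self):
        a = np.array([1] + [0] * 9, dtype=np.int8)
        b = np.array([0] + [0] * 9, dtype=np.int8)
        r = replicate_error_rates([(a, b)])
        assert r.global_rate == pytest.approx(10.0)
        # ordering 1: site 0 is het in a -> het error 1/1; ordering 2: hom in
        # b -> hom error 1/10.  Pooled: hom 1/19, het 1/1... conditioned counts
        assert r.n_sites_compared == 10

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, 500).astype(np.int8)
        b = a.copy()
        flip = rng.random(500) < 0.05
        b[flip] = (b[flip] + 1) % 3
        r1 = replicate_error_rates([(a, b)])
        r2 = replicate_error_rates([(b, a)])
        assert r1.global_rate == r2.global_rate
        assert r1.homozygous == r2.homozygous
        assert r1.heterozygous == r2.heterozygous

    def test_no_cocalled(self):
        a = np.full(5, MISSING, dtype=np.int8)
        with pytest.raises(UndefinedRateError):
            replicate_error_rates([(a, a.copy())])

    def test_recovery_of_injected_rate(self, tmp_path):
        from seedtrace.scenarios import two_esu_scenario
        from seedtrace.simulate import ScenarioConfig, generate_scenario

        base = two_esu_scenario(seed=42, n_individuals=4, n_loci=10_000)
        cfg = ScenarioConfig(
            esus=base.esus, populations=base.populations, n_loci=10_000,
            replicate_pairs=1, injected_error_rate=0.02, rng_seed=42,
        )
        G, _, paths = generate_scenario(cfg, tmp_path)
        R = read_vcf(paths["replicates"][0])
        idx = {ind: i for i, ind in enumerate(G.individual_ids)}
        pairs = [
            (G.dosages[idx[rid.removesuffix("_rep")]], R.dosages[j])
            for j, rid in enumerate(R.individual_ids)
        ]
        r = replicate_error_rates(pairs)
        se = 100 * np.sqrt(0.02 * 0.98 / r.n_sites_compared)
        assert abs(r.global_rate - 2.0) < 3 * se
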
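"""CNV FST, VST variance decomposition, dual-caller cross-validation,
outlier geometry and the FST–VST association."""

import numpy as np
import pytest

import divergescan as ds


def _callset(intervals, samples=None, genotypes=None):
    samples = samples or ["s0", "s1"]
    calls = []
    for iv in intervals:
        chrom, start, end, svtype = iv
        gt = genotypes if genotypes is not None else np.zeros(len(samples))
        calls.append(ds.CNVCall(chrom, start, end, svtype, 50.0, gt))
    return ds.CNVCallset(calls, samples)


def _popmap_2x20():
    return ds.PopulationMap.from_dict(
        {f"a{i}": "popA" for i in range(20)} |
        {f"b{i}": "popB" for i in range(20)})


# ---------------------------------------------------------------- CNV FST

def test_cnv_fst_fixed_difference():
    pm = _popmap_2x20()
    samples = list(pm.table["sample"])
    gt = np.r_[np.full(20, 2), np.zeros(20)].astype(np.int8)
    cs = ds.CNVCallset([ds.CNVCall("c", 0, 100, "DEL", 50.0, gt)], samples)
    fst = ds.cnv_fst(cs, pm, "popA", "popB")
    assert fst["fst"].iloc[0] >= 0.97


def test_cnv_fst_identical_frequencies_clamped_zero():
    pm = _popmap_2x20()
    samples = list(pm.table["sample"])
    gt = np.tile(np.r_[np.ones(10), np.zeros(10)], 2).astype(np.int8)
    cs = ds.CNVCallset([ds.CNVCall("c", 0, 100, "DUP", 50.0, gt)], samples)
    fst = ds.cnv_fst(cs, pm, "popA", "popB")
    assert fst["fst"].iloc[0] == 0.0
    assert fst["fst_raw"].iloc[0] <= 0


def test_cnv_fst_equals_snp_path_exactly():
    """A CNV coded 0/1/2 carrier dosage gives the same per-locus value as
    the SNP path on the equivalently coded genotypes."""
    rng = np.random.default_rng(4)
    pm = _popmap_2x20()
    samples = list(pm.table["sample"])
    gt = rng.integers(0, 3, 40).astype(np.int8)
    cs = ds.CNVCallset([ds.CNVCall("c", 0, 100, "DEL", 50.0, gt)], samples)
    fst_cnv = ds.cnv_fst(cs, pm, "popA", "popB")["fst"].iloc[0]
    # SNP path: same dosages as diploid allele pairs
    pairs = np.array([{0: (0, 0), 1: (0, 1), 2: (1, 1)}[g] for g in gt],
                     dtype=np.int8)
    a, b, c = ds.site_wc_fst_components(pairs[:20], pairs[20:])
    assert fst_cnv == max(0.0, a / (a + b + c))


def test_cnv_fst_missing_population_is_nan():
    pm = _popmap_2x20()
    samples = list(pm.table["sample"])
    gt = np.r_[np.full(20, -1), np.ones(20)].astype(np.int8)
    cs = ds.CNVCallset([ds.CNVCall("c", 0, 100, "DEL", 50.0, gt)], samples)
    assert np.isnan(ds.cnv_fst(cs, pm, "popA", "popB")["fst"].iloc[0])


# ---------------------------------------------------------------- VST

def test_vst_perfect_partition():
    pm = ds.PopulationMap.from_dict(
        {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)})
    samples = list(pm.table["sample"])
    copies = np.r_[np.full(5, 2), np.full(5, 4)]
    rec = ds.vst(copies, pm, samples)
    assert rec.vst == pytest.approx(1.0)
    assert rec.v_within == pytest.approx(0.0)


def test_vst_null_large_n():
    rng = np.random.default_rng(6)
    pm = ds.PopulationMap.from_dict(
        {f"a{i}": "A" for i in range(200)} |
        {f"b{i}": "B" for i in range(200)})
    samples = list(pm.table["sample"])
    copies = rng.poisson(2, 400)
    rec = ds.vst(copies, pm, samples)
    assert abs(rec.vst) < 0.05


def test_vst_equals_bruteforce_decomposition():
    """VST equals an explicit variance decomposition computed from first
    principles, to 1e-12."""
    pm = ds.PopulationMap.from_dict(
        {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)})
    samples = list(pm.table["sample"])
    copies = np.array([2, 2, 3, 3, 4, 4, 5, 5])
    rec = ds.vst(copies, pm, samples)

    def var(x):  # sample variance, n−1 denominator
        m = sum(x) / len(x)
        return sum((v - m) ** 2 for v in x) / (len(x) - 1)

    v_t = var(list(copies))
    v_s = (4 / 8) * var([2, 2, 3, 3]) + (4 / 8) * var([4, 4, 5, 5])
    assert rec.vst == pytest.approx((v_t - v_s) / v_t, abs=1e-12)


def test_vst_undefined_cases():
    pm = ds.PopulationMap.from_dict(
        {"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
    samples = ["a0", "a1", "b0", "b1"]
    # zero total variance
    assert np.isnan(ds.vst(np.array([2, 2, 2, 2]), pm, samples).vst)
    # a population with <2 called samples
    assert np.isnan(ds.vst(np.array([2, -1, 3, 4]), pm, samples).vst)


def test_vst_not_clamped_below_zero():
    """Slightly negative VST (within-pop variance exceeding total) is
    reported as-is."""
    pm = ds.PopulationMap.from_dict(
        {"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
    rec = ds.vst(np.array([1, 3, 2, 2]), pm, ["a0", "a1", "b0", "b1"])
    assert rec.vst < 0


# ---------------------------------------------------------------- overlap

def test_cross_validation_boundary_strict():
    """Intersection exactly 50% of the primary length is dropped under
    strict '>'; one extra base retains it."""
    primary = _callset([("c", 0, 100, "DEL")])
    exactly_half = _callset([("c", 50, 100, "DEL")])
    kept, _ = ds.cross_validate_calls(primary, exactly_half)
    assert len(kept) == 0
    one_more = _callset([("c", 49, 100, "DEL")])
    kept, _ = ds.cross_validate_calls(primary, one_more)
    assert len(kept) == 1


def test_cross_validation_identity_and_disjoint():
    primary = _callset([("c", 0, 100, "DEL"), ("c", 500, 600, "DUP")])
    kept, report = ds.cross_validate_calls(primary, primary)
    assert len(kept) == 2
    disjoint = _callset([("c", 1000, 1100, "DEL")])
    kept, _ = ds.cross_validate_calls(primary, disjoint)
    assert len(kept) == 0


def test_cross_validation_svtype_must_agree():
    primary = _callset([("c", 0, 100, "DEL")])
    other_type = _callset([("c", 0, 100, "DUP")])
    kept, _ = ds.cross_validate_calls(primary, other_type)
    assert len(kept) == 0


def test_cross_validation_monotone_in_threshold():
    rng = np.random.default_rng(8)
    ivs_p = [("c", int(s), int(s) + int(l), "DEL")
             for s, l in zip(rng.integers(0, 10_000, 50),
                             rng.integers(10, 200, 50))]
    ivs_s = [("c", int(s), int(s) + int(l), "DEL")
             for s, l in zip(rng.integers(0, 10_000, 50),
                             rng.integers(10, 200, 50))]
    primary, secondary = _callset(ivs_p), _callset(ivs_s)
    retained = [len(ds.cross_validate_calls(primary, secondary, t)[0])
                for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
    assert retained == sorted(retained, reverse=True)


def test_cross_validation_matches_bruteforce_oracle():
    """Interval-tree retention equals a quadratic-time direct
    intersection scan."""
    rng = np.random.default_rng(13)
    def rand_set(n):
        return _callset([("c", int(s), int(s) + int(l),
                          "DEL" if rng.random() < 0.5 else "DUP")
                         for s, l in zip(rng.integers(0, 50_000, n),
                                         rng.integers(5, 500, n))])
    primary, secondary = rand_set(150), rand_set(150)
    kept, _ = ds.cross_validate_calls(primary, secondary, 0.5)
    expected = []
    for p in primary.calls:
        for s in secondary.calls:
            if p.svtype != s.svtype or p.chrom != s.chrom:
                continue
            inter = min(p.end, s.end) - max(p.start, s.start)
            if inter > 0.5 * p.length:
                expected.append(p)
                break
    assert [(c.start, c.end) for c in kept.calls] == \
           [(c.start, c.end) for c in expected]


def test_jitter_free_validation_retains_everything():
    pm = ds.PopulationMap.from_dict(
        {f"s{i}": ("p1" if i < 5 else "p2") for i in range(10)})
    loci = ds.simulate_cnv_truth(n_loci=40, pop_names=("p1", "p2"), seed=3)
    a, b, _ = ds.simulate_cnv_callsets(loci, pm, jitter_bp=0,
                                       fdr_a=0.0, fdr_b=0.0, seed=5)
    kept, _ = ds.cross_validate_calls(a, b)
    assert len(kept) == len(a)


def test_spurious_calls_filtered_at_expected_rate():
    """With half of callset A spurious and modest jitter, the retained
    fraction approximates the true-call fraction."""
    pm = ds.PopulationMap.from_dict(
        {f"s{i}": ("p1" if i < 10 else "p2") for i in range(20)})
    loci = ds.simulate_cnv_truth(n_loci=200, genome_length=40_000_000,
                                 pop_names=("p1", "p2"),
                                 mean_length=5000, seed=17)
    # jitter ≈ 10% of typical length
    a, b, _ = ds.simulate_cnv_callsets(loci, pm, jitter_bp=500,
                                       fdr_a=0.5, fdr_b=0.0, seed=18,
                                       genome_length=40_000_000)
    kept, _ = ds.cross_validate_calls(a, b)
    retained_fraction = len(kept) / len(a)
    true_fraction = len(loci) / len(a)
    assert abs(retained_fraction - true_fraction) <= 0.1


# ---------------------------------------------------------------- outliers

def test_cnv_outliers_planted_fixed_differences():
    rng = np.random.default_rng(19)
    fst = rng.uniform(0, 0.1, 1000)
    planted = rng.choice(1000, 10, replace=False)
    fst[planted] = 0.98
    out = ds.cnv_outliers(fst, q=0.99)
    assert set(planted) <= set(out.indices)
    s = np.sort(fst)
    h = 999 * 0.99
    lo = int(h)
    assert out.threshold == pytest.approx(
        s[lo] + (h - lo) * (s[lo + 1] - s[lo]))


# ---------------------------------------------------------------- geometry

def test_outlier_geometry_examples():
    samples = ["s0"]
    cs = ds.CNVCallset([
        ds.CNVCall("c", 2100, 2200, "DEL", 1.0, np.zeros(1)),  # inside gene
        ds.CNVCall("c", 1000, 1100, "DEL", 1.0, np.zeros(1)),  # 900 bp away
    ], samples)
    per_call, agg = ds.summarize_outlier_geometry(
        cs, [("c", 2000, 3000)])
    assert per_call["nearest_gene_bp"].tolist() == [0, 900]
    assert per_call["overlaps_gene"].tolist() == [True, False]
    assert agg.loc[agg["svtype"] == "DEL", "n_overlapping_genes"].iloc[0] == 1


def test_outlier_geometry_hand_enumerated():
    """Aggregate geometry equals a hand-enumerated nearest-neighbor scan
    over 5 CNVs and 3 genes."""
    cnvs = [("c", 0, 10), ("c", 100, 150), ("c", 220, 230),
            ("c", 400, 500), ("d", 5, 15)]
    genes = [("c", 20, 50), ("c", 200, 210), ("c", 450, 460)]
    cs = ds.CNVCallset([ds.CNVCall(ch, s, e, "DUP", 1.0, np.zeros(1))
                        for ch, s, e in cnvs], ["s0"])
    per_call, agg = ds.summarize_outlier_geometry(cs, genes)
    # by hand: [0,10) → gap 10 to [20,50); [100,150) → gap 50 to [200,210);
    # [220,230) → gap 10 back to [200,210); [400,500) overlaps [450,460) → 0;
    # chrom d has no genes on it → nearest across chroms is undefined → NaN
    assert per_call["nearest_gene_bp"].tolist()[:4] == [10, 50, 10, 0]
    assert np.isnan(per_call["nearest_gene_bp"].iloc[4])
    assert agg["mean_length"].iloc[0] == pytest.approx(
        np.mean([10, 50, 10, 100, 10]))


def test_outlier_geometry_no_genes():
    cs = ds.CNVCallset([ds.CNVCall("c", 0, 10, "DEL", 1.0, np.zeros(1))],
                       ["s0"])
    per_call, _ = ds.summarize_outlier_geometry(cs, [])
    assert np.isnan(per_call["nearest_gene_bp"].iloc[0])


# ---------------------------------------------------------------- FST–VST

def test_association_monotone_is_perfect():
    fst = np.linspace(0, 0.5, 50)
    rho, _ = ds.fst_vst_association(fst, fst ** 2)
    assert rho == pytest.approx(1.0)


def test_association_null_is_small():
    rng = np.random.default_rng(23)
    rho, _ = ds.fst_vst_association(rng.random(1000), rng.random(1000))
    assert abs(rho) < 0.1


def test_association_planted_shared_signal():
    """Loci with population-differentiated copy numbers push both FST and
    VST up, so the simulated design yields ρ > 0 with p < 0.01."""
    pm = ds.PopulationMap.from_dict(
        {f"a{i}": "pop1" for i in range(20)} |
        {f"b{i}": "pop2" for i in range(20)})
    loci = ds.simulate_cnv_truth(n_loci=200, genome_length=40_000_000,
                                 n_differentiated=40, seed=29)
    a, _, cn = ds.simulate_cnv_callsets(loci, pm, seed=31,
                                        genome_length=40_000_000)
    fst = ds.cnv_fst(a, pm, "pop1", "pop2")
    vs = ds.vst_scan(cn, pm)
    rho, p = ds.fst_vst_association(fst["fst"].to_numpy(),
                                    vs["vst"].to_numpy())
    assert rho > 0
    assert p < 0.01


def test_association_too_few_loci_rejected():
    with pytest.raises(ValueError):
        ds.fst_vst_association(np.ones(5), np.ones(5))
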
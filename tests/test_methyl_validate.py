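"""Detection filtering, replicate concordance, region comparison."""

import numpy as np
import pandas as pd
import pytest

from crossprobe.fixtures import simulate_region_betas
from crossprobe.methyl_validate import (
    BetaMatrix,
    MethylRegion,
    ValidationError,
    detection_filter,
    pairwise_pearson,
    read_regions,
    region_overlap_compare,
)


def _matrix(beta_rows, p_rows=None, probes=None, samples=None):
    beta = np.asarray(beta_rows, dtype=float)
    probes = probes or [f"p{i}" for i in range(beta.shape[0])]
    samples = samples or [f"S{j}" for j in range(beta.shape[1])]
    p = np.asarray(p_rows, dtype=float) if p_rows is not None else np.full_like(beta, 1e-3)
    return BetaMatrix(
        beta=pd.DataFrame(beta, index=probes, columns=samples),
        detection_p=pd.DataFrame(p, index=probes, columns=samples),
    )


class TestBetaMatrix:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            _matrix([[0.5, 1.2]])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            _matrix([[0.1, 0.2], [0.3, 0.4]], probes=["p", "p"])

    def test_tsv_round_trip(self, tmp_path):
        m = _matrix([[0.1, 0.9], [0.5, 0.25]])
        m.write_tsv(tmp_path / "b.tsv", tmp_path / "p.tsv")
        back = BetaMatrix.read_tsv(tmp_path / "b.tsv", tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(back.beta, m.beta)


class TestDetectionFilter:
    def test_single_failing_sample_removes_probe(self):
        p = [[0.001] * 5, [0.001, 0.02, 0.001, 0.001, 0.001]]
        m = _matrix([[0.5] * 5, [0.5] * 5], p)
        kept, report = detection_filter(m)
        assert kept.probe_ids == ["p0"]
        assert report["n_input"] == 2 and report["n_detected"] == 1

    def test_all_detected_all_kept(self):
        m = _matrix(np.full((4, 5), 0.3), np.full((4, 5), 0.001))
        kept, _ = detection_filter(m)
        assert kept.probe_ids == m.probe_ids

    def test_threshold_is_strict(self):
        m = _matrix([[0.5] * 2], [[0.01, 0.001]])
        kept, _ = detection_filter(m, p_threshold=0.01)
        assert kept.probe_ids == []

    def test_autosomal_restriction_counts(self):
        m = _matrix(np.full((10, 5), 0.4))
        chrom_map = {f"p{i}": ("chrX" if i < 2 else f"chr{i}") for i in range(10)}
        kept, report = detection_filter(m, autosomal_only=True, chrom_map=chrom_map)
        assert report["n_autosomal"] == 8
        assert len(kept.probe_ids) == 8

    def test_scaffold_dropped_as_non_autosomal(self):
        m = _matrix(np.full((2, 3), 0.4))
        chrom_map = {"p0": "chr3", "p1": "scaffold_17"}
        kept, _ = detection_filter(m, autosomal_only=True, chrom_map=chrom_map)
        assert kept.probe_ids == ["p0"]

    def test_unmapped_probe_is_error(self):
        m = _matrix(np.full((2, 3), 0.4))
        with pytest.raises(ValidationError, match="absent"):
            detection_filter(m, autosomal_only=True, chrom_map={"p0": "chr1"})

    def test_idempotent_and_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.uniform(0, 1, (30, 5)), rng.uniform(0, 0.05, (30, 5)))
        k1, _ = detection_filter(m, 0.02)
        k2, _ = detection_filter(k1, 0.02)
        assert k1.probe_ids == k2.probe_ids
        stricter, _ = detection_filter(m, 0.005)
        assert set(stricter.probe_ids) <= set(k1.probe_ids)


class TestPairwisePearson:
    def test_duplicated_columns_r_one(self):
        x = [0.1, 0.5, 0.9, 0.3]
        m = _matrix(np.column_stack([x, x, np.add(x, 0.05)]))
        rep = pairwise_pearson(m)
        assert rep.corr.iloc[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        x = np.array([0.1, 0.5, 0.9, 0.3])
        m = _matrix(np.column_stack([x, 1 - x]))
        rep = pairwise_pearson(m)
        assert rep.average_r == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        """R for x=[.1,.5,.9], y=[.2,.4,1.0] from the sum-form Pearson formula."""
        x = np.array([0.1, 0.5, 0.9])
        y = np.array([0.2, 0.4, 1.0])
        n = 3
        expected = (n * np.sum(x * y) - x.sum() * y.sum()) / np.sqrt(
            (n * np.sum(x**2) - x.sum() ** 2) * (n * np.sum(y**2) - y.sum() ** 2)
        )
        m = _matrix(np.column_stack([x, y]))
        rep = pairwise_pearson(m)
        assert rep.average_r == pytest.approx(float(expected))

    def test_constant_column_nan_excluded(self):
        m = _matrix(np.column_stack([[0.1, 0.5, 0.9], [0.4, 0.4, 0.4],
                                     [0.2, 0.6, 1.0]]))
        rep = pairwise_pearson(m)
        assert np.isnan(rep.corr.iloc[0, 1])
        assert not np.isnan(rep.average_r)

    def test_stratified_by_type(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.uniform(0, 1, (20, 4)))
        types = {f"p{i}": ("I" if i < 8 else "II") for i in range(20)}
        rep = pairwise_pearson(m, probe_types=types)
        assert set(rep.by_type) == {"I", "II"}

    def test_too_few_probes_is_error(self):
        m = _matrix([[0.1, 0.2]])
        with pytest.raises(ValidationError):
            pairwise_pearson(m)

    def test_invariant_under_probe_permutation(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.uniform(0, 1, (15, 4)))
        rep1 = pairwise_pearson(m)
        perm = list(rng.permutation(m.probe_ids))
        rep2 = pairwise_pearson(m.subset(perm))
        assert rep1.average_r == pytest.approx(rep2.average_r)
        assert (rep1.corr.abs().to_numpy() <= 1 + 1e-12).all()


REGIONS = [
    MethylRegion("chr1", 100, 200, 0.8, "hippocampus"),
    MethylRegion("chr1", 300, 400, 0.2, "hippocampus"),
]


class TestRegionOverlap:
    def test_containment_and_boundaries(self):
        coords = {"in": ("chr1", 150), "edge": ("chr1", 200), "out": ("chr2", 150)}
        m = _matrix(np.full((3, 2), 0.5), probes=["in", "edge", "out"])
        res = region_overlap_compare(coords, m, REGIONS)
        assert res.n_probes_in_regions == 1
        assert list(res.pairs.probe_id) == ["in"]

    def test_hand_enumerated_count(self):
        coords = {"a": ("chr1", 120), "b": ("chr1", 350), "c": ("chr1", 399),
                  "d": ("chr1", 250)}
        m = _matrix(np.full((4, 2), 0.5), probes=list(coords))
        res = region_overlap_compare(coords, m, REGIONS)
        assert res.n_probes_in_regions == 3

    def test_probe_in_overlapping_regions_flagged(self):
        regions = REGIONS + [MethylRegion("chr1", 150, 320, 0.5, "cortex")]
        coords = {"a": ("chr1", 160)}
        m = _matrix(np.full((1, 2), 0.5), probes=["a"])
        res = region_overlap_compare(coords, m, regions)
        assert len(res.pairs) == 2
        assert (res.pairs.n_regions == 2).all()

    def test_r_per_label_recovers_levels(self):
        rng = np.random.default_rng(8)
        regions = [MethylRegion("chr1", i * 1000, i * 1000 + 500,
                                float(rng.uniform(0.1, 0.9)), "lobeA")
                   for i in range(12)]
        coords = {f"p{i}": ("chr1", i * 1000 + 250) for i in range(12)}
        levels = {f"p{i}": regions[i].level for i in range(12)}
        m = simulate_region_betas(levels, n_samples=5, sigma=0.01, seed=1)
        res = region_overlap_compare(coords, m, regions)
        assert res.r_by_label["lobeA"] > 0.99

    def test_read_regions_tsv(self, tmp_path):
        p = tmp_path / "regions.tsv"
        p.write_text("chrom\tstart\tend\tlevel\tlabel\n"
                     "chr1\t100\t200\t0.8\thippocampus\n")
        regs = read_regions(p)
        assert regs == [MethylRegion("chr1", 100, 200, 0.8, "hippocampus")]


class TestConcordanceRecovery:
    def test_r_increases_as_noise_vanishes(self):
        """Recovered correlation climbs toward 1 as beta noise shrinks,
        and tracks the analytic attenuation sigma_L/sqrt(sigma_L^2+sigma^2/n)."""
        rng = np.random.default_rng(42)
        n_probes, n_samples = 60, 5
        regions = [MethylRegion("chr1", i * 500, i * 500 + 300,
                                float(rng.uniform(0.1, 0.9)), "lobe")
                   for i in range(n_probes)]
        coords = {f"p{i}": ("chr1", i * 500 + 100) for i in range(n_probes)}
        levels = {f"p{i}": regions[i].level for i in range(n_probes)}
        sigmas = [0.3, 0.15, 0.05, 0.01]
        mean_r = []
        for s_i, sigma in enumerate(sigmas):
            rs = [
                region_overlap_compare(
                    coords,
                    simulate_region_betas(levels, n_samples, sigma,
                                          seed=1000 * s_i + rep),
                    regions,
                ).overall_r
                for rep in range(10)
            ]
            mean_r.append(float(np.mean(rs)))
        assert all(b > a for a, b in zip(mean_r, mean_r[1:]))
        assert mean_r[-1] > 0.99
        # analytic check away from the clipping regime
        lv = np.array(list(levels.values()))
        sigma_l = lv.std()
        expected = sigma_l / np.sqrt(sigma_l**2 + 0.05**2 / n_samples)
        assert mean_r[2] == pytest.approx(float(expected), abs=0.02)
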
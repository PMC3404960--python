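"""The synthetic-data generators and their statistical guarantees."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from silicomap.io import write_fasta
from silicomap.linkmap import haldane_r
from silicomap.simdata import (
    SimConfig,
    make_truth_map,
    simulate_f2,
    simulate_phenotypes,
    simulate_two_line_reads,
)
from silicomap.ssrscan import find_tracts


def _fasta_bytes(reads):
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "r.fasta"
        write_fasta(reads, p)
        return p.read_bytes()


class TestReadSimulator:
    def test_seed_determinism_byte_identical(self):
        cfg = SimConfig(n_ssr_loci=10, n_te_sites=5, seed=42)
        r1, _ = simulate_two_line_reads(cfg)
        r2, _ = simulate_two_line_reads(SimConfig(n_ssr_loci=10, n_te_sites=5, seed=42))
        assert _fasta_bytes(r1) == _fasta_bytes(r2)
        r3, _ = simulate_two_line_reads(SimConfig(n_ssr_loci=10, n_te_sites=5, seed=43))
        assert _fasta_bytes(r1) != _fasta_bytes(r3)

    def test_zero_polymorphic_fraction(self):
        cfg = SimConfig(n_ssr_loci=25, n_te_sites=0, frac_polymorphic=0.0, seed=1)
        _, truth = simulate_two_line_reads(cfg)
        for locus in truth.ssr_loci:
            counts = list(locus.repeat_counts.values())
            assert counts[0] == counts[1]
            assert not locus.polymorphic

    def test_noise_free_reads_carry_exact_tracts(self):
        cfg = SimConfig(n_ssr_loci=1, n_te_sites=0, read_error_rate=0.0,
                        motif_pool=(("AC", 1.0),), frac_polymorphic=1.0,
                        reads_per_locus_per_line=1, seed=2)
        reads, truth = simulate_two_line_reads(cfg)
        locus = truth.ssr_loci[0]
        for r in reads:
            tracts = find_tracts(r.seq)
            assert len(tracts) == 1
            assert tracts[0].motif == "AC"
            assert tracts[0].repeat_count == locus.repeat_counts[r.line]

    def test_te_reads_only_from_carriers(self):
        cfg = SimConfig(n_ssr_loci=0, n_te_sites=30, frac_te_line_specific=0.5, seed=3)
        reads, truth = simulate_two_line_reads(cfg)
        emitted = {(r.line, r.read_id.split("|")[1]) for r in reads}
        for site in truth.te_sites:
            for line, present in site.presence.items():
                assert ((line, site.site_id) in emitted) == present

    def test_flank_20mer_uniqueness(self):
        cfg = SimConfig(n_ssr_loci=40, n_te_sites=0, read_error_rate=0.0, seed=4)
        _, truth = simulate_two_line_reads(cfg)
        seen = set()
        for locus in truth.ssr_loci:
            for flank in (locus.left_flank, locus.right_flank):
                kmers = {flank[i:i + 20] for i in range(len(flank) - 19)}
                assert not (kmers & seen)
                seen |= kmers

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_two_line_reads(SimConfig(motif_pool=(("ACX", 1.0),)))
        with pytest.raises(ValueError):
            simulate_two_line_reads(SimConfig(frac_polymorphic=1.5))
        with pytest.warns(UserWarning):
            SimConfig(repeat_count_range=(3, 10)).validate()


class TestF2Simulator:
    def test_zero_distance_no_recombinants(self):
        tm = {"G1": [("L1", 0.0), ("L2", 0.001)]}
        gm = simulate_f2(tm, 50, seed=5)
        # r = inverse-Haldane of 0.001 cM ~ 1e-5: recombinants essentially impossible
        assert (gm["L1"] == gm["L2"]).all()

    def test_unlinked_groups_half_recombination(self):
        tm = {"G1": [("L1", 0.0)], "G2": [("L2", 0.0)]}
        gm = simulate_f2(tm, 1000, seed=6)
        # count recombinant gametes via the joint genotype distribution:
        # parental double homozygotes aa/bb occur with prob ((1-r)/2)^2 each
        n_aa_bb = ((gm["L1"] == "a") & (gm["L2"] == "a")).sum() + (
            (gm["L1"] == "b") & (gm["L2"] == "b")).sum()
        p = 2 * 0.0625
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(n_aa_bb / 1000 - p) <= 3 * se

    def test_interval_recombination_matches_inverse_haldane(self):
        # 34.657 cM -> r = 0.25; empirical recombinant fraction within 3 s.e.
        tm = {"G1": [("L1", 0.0), ("L2", 34.657)]}
        n = 500
        gm = simulate_f2(tm, n, seed=7)
        r_expected = haldane_r(34.657)
        assert r_expected == pytest.approx(0.25, abs=1e-4)
        # estimate recombinant gametes from unambiguous classes
        from silicomap.linkmap import estimate_rf_f2

        r_hat = estimate_rf_f2(gm["L1"], gm["L2"]).r
        se = np.sqrt(0.25 * 0.75 / (2 * n))
        assert abs(r_hat - 0.25) <= 3 * se

    def test_mendelian_ratios_undistorted(self):
        tm = make_truth_map(1, 5, 20.0)
        gm = simulate_f2(tm, 500, seed=8)
        for locus in gm.columns:
            counts = gm[locus].value_counts()
            obs = [counts.get(c, 0) for c in "ahb"]
            _, p = stats.chisquare(obs, [125, 250, 125])
            assert p > 0.01

    def test_distortion_shifts_ratio(self):
        tm = {"G1": [("L1", 0.0)]}
        gm = simulate_f2(tm, 600, seed=9, distortion={"L1": {"a": 0.1, "h": 1.0, "b": 1.0}})
        counts = gm["L1"].value_counts()
        obs = [counts.get(c, 0) for c in "ahb"]
        _, p = stats.chisquare(obs, [150, 300, 150])
        assert p < 0.001

    def test_missing_rate_and_codes(self):
        tm = make_truth_map(1, 4, 10.0)
        gm = simulate_f2(tm, 200, seed=10, missing_rate=0.1,
                         dominant_loci={"M001": "c", "M002": "d"})
        assert set(gm["M001"]) <= {"a", "c", "-"}
        assert set(gm["M002"]) <= {"b", "d", "-"}
        frac_missing = (gm == "-").to_numpy().mean()
        assert 0.05 < frac_missing < 0.15

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            simulate_f2({"G1": [("L1", 0.0)]}, 1)
        with pytest.raises(ValueError):
            simulate_f2({"G1": [("L1", 5.0), ("L2", 1.0)]}, 10)


class TestPhenotypeSimulator:
    def test_zero_noise_equals_dosage(self):
        tm = {"G1": [("Q", 0.0)]}
        gm = simulate_f2(tm, 80, seed=11)
        ph = simulate_phenotypes(gm, {"qtls": [{"locus": "Q", "a": 1.0, "d": 0.0}],
                                      "sigma": 0.0}, seed=12)
        dosage = gm["Q"].map({"a": -1.0, "h": 0.0, "b": 1.0})
        assert np.allclose(ph["trait"], dosage)

    def test_heterozygote_at_one_locus_is_low_class(self):
        gm = pd.DataFrame({"A": ["b", "b", "h", "a"], "B": ["b", "h", "b", "b"]},
                          index=list("wxyz"))
        ph = simulate_phenotypes(gm, {"epistatic_pair": ("A", "B"),
                                      "high_mean": 40.0, "low_mean": 1.0,
                                      "eps_sigma": 0.0}, seed=13)
        assert ph.loc["w", "epistatic_trait"] == pytest.approx(40.0)
        for ind in "xyz":
            assert ph.loc[ind, "epistatic_trait"] == pytest.approx(1.0)

    def test_double_homozygote_fraction_one_sixteenth(self):
        tm = {"G1": [("A", 0.0)], "G2": [("B", 0.0)]}
        gm = simulate_f2(tm, 1600, seed=14)
        frac = ((gm["A"] == "b") & (gm["B"] == "b")).mean()
        res = stats.binomtest(int(frac * 1600), 1600, 1 / 16)
        assert res.pvalue > 0.01

    def test_unknown_locus_rejected(self):
        gm = pd.DataFrame({"A": ["a", "h"]})
        with pytest.raises(ValueError):
            simulate_phenotypes(gm, {"qtls": [{"locus": "Z", "a": 1.0}]})
        with pytest.raises(ValueError):
            simulate_phenotypes(gm, {"epistatic_pair": ("A", "Z")})

    def test_seed_determinism(self):
        tm = make_truth_map(1, 3, 10.0)
        gm = simulate_f2(tm, 50, seed=15)
        model = {"qtls": [{"locus": "M000", "a": 1.0, "d": 0.2}], "sigma": 1.0}
        a = simulate_phenotypes(gm, model, seed=16)
        b = simulate_phenotypes(gm, model, seed=16)
        pd.testing.assert_frame_equal(a, b)
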
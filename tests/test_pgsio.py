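"""Trio transmission resolution, haplotypic scoring and score scaling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pgsnurture import SimConfig, export_fixture, extract_family_table, simulate_population
from pgsnurture import pgsio
from pgsnurture.pgsio import AMBIGUOUS, MENDELIAN_ERROR, resolve_transmission

SCORES = ["T_p", "NT_p", "T_m", "NT_m"]


def brute_force_transmissions(df, dm, do):
    """Enumerate all Mendelian-consistent (t_p, t_m) pairs for dosages."""
    alleles = lambda d: [0] if d == 0 else ([1] if d == 2 else [0, 1])
    return sorted({(tp, tm) for tp in alleles(df) for tm in alleles(dm) if tp + tm == do})


class TestResolveTransmission:
    def test_forced_case(self):
        assert resolve_transmission(2, 0, 1) == (1, 0)

    def test_triple_het_is_ambiguous(self):
        assert resolve_transmission(1, 1, 1) is AMBIGUOUS

    def test_impossible_is_mendelian_error(self):
        assert resolve_transmission(2, 2, 1) is MENDELIAN_ERROR

    def test_exhaustive_against_enumeration(self):
        for df, dm, do in itertools.product(range(3), range(3), range(3)):
            options = brute_force_transmissions(df, dm, do)
            got = resolve_transmission(df, dm, do)
            if not options:
                assert got is MENDELIAN_ERROR
            elif len(options) > 1:
                assert got is AMBIGUOUS
            else:
                assert got == options[0]

    def test_phased_reads_offspring_haplotype(self):
        assert resolve_transmission(1, 1, (1, 0), phased=True) == (1, 0)
        assert resolve_transmission(0, 1, (1, 0), phased=True) is MENDELIAN_ERROR


class TestRoundTrip:
    def test_phased_scores_match_simulator(self, small_fixture_pops, exported_fixture):
        paths = exported_fixture
        trios = pgsio.load_trio_genotypes(paths["vcf"], paths["pedigree"])
        assert trios.phased
        weights = pgsio.read_weight_table(paths["weights"])
        scores = pgsio.haplotypic_scores(trios, weights)
        truth = extract_family_table(small_fixture_pops)
        for col in SCORES:
            np.testing.assert_allclose(scores[col], truth[col], atol=1e-9)
        assert (scores.n_mendelian_errors == 0).all()
        assert (scores.n_ambiguous == 0).all()

    def test_vcf_is_well_formed(self, exported_fixture):
        lines = exported_fixture["vcf"].read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        header = next(l for l in lines if l.startswith("#CHROM"))
        assert header.split("\t")[:9] == [
            "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
        ]
        body = [l for l in lines if not l.startswith("#")]
        weights = pd.read_csv(exported_fixture["weights"], sep="\t")
        assert len(body) == len(weights)          # weights rows = m_obs = VCF records
        assert all("|" in fld for fld in body[0].split("\t")[9:])

    def test_phased_and_unphased_agree_where_resolvable(self, exported_fixture):
        paths = exported_fixture
        weights = pgsio.read_weight_table(paths["weights"])
        phased = pgsio.haplotypic_scores(
            pgsio.load_trio_genotypes(paths["vcf"], paths["pedigree"]), weights
        )
        unphased = pgsio.haplotypic_scores(
            pgsio.load_trio_genotypes(paths["vcf"], paths["pedigree"], phased=False),
            weights,
        )
        no_amb = unphased.n_ambiguous == 0
        assert no_amb.sum() > 10
        for col in SCORES:
            np.testing.assert_allclose(
                unphased.loc[no_amb, col], phased.loc[no_amb, col], atol=1e-9
            )

    def test_unphased_reconstruction_high_fidelity(self, tmp_path):
        # many common variants: triple-het ambiguity attenuates but the
        # reconstructed transmitted score still tracks the truth closely
        cfg = SimConfig(n_families=300, delta=0.4, f=0.1, r_mate=0.0, V_eps=0.5,
                        m_obs=1000, m_lat=1, maf_range=(0.2, 0.5),
                        n_generations=2, seed=11)
        pops = simulate_population(cfg)
        paths = export_fixture(pops, out_dir=tmp_path)
        trios = pgsio.load_trio_genotypes(paths["vcf"], paths["pedigree"], phased=False)
        weights = pgsio.read_weight_table(paths["weights"])
        scores = pgsio.haplotypic_scores(trios, weights, ambiguity_policy="drop")
        truth = extract_family_table(pops)
        corr = np.corrcoef(scores.T_p, truth.T_p)[0, 1]
        # analytic attenuation oracle.  Per locus the transmitted allele t is
        # Bernoulli(p); a site is dropped when all three members are
        # heterozygous, and P(t=1 and ambiguous) = (2pq)^2/4, so the kept
        # contribution t*1[kept] is Bernoulli(p - (2pq)^2/4).  Summing
        # beta^2-weighted per-locus moments gives the expected correlation.
        var_df = pops[0].variants.query("observed")
        p, b = var_df.maf.to_numpy(), var_df.weight.to_numpy()
        p_kept1 = p - (2 * p * (1 - p)) ** 2 / 4
        cov_term = (b**2 * p_kept1 * (1 - p)).sum()
        var_sub = (b**2 * p_kept1 * (1 - p_kept1)).sum()
        var_full = (b**2 * p * (1 - p)).sum()
        predicted = cov_term / np.sqrt(var_sub * var_full)
        assert corr > 0.85
        assert corr == pytest.approx(predicted, abs=0.02)

    def test_ambiguity_rate_matches_triple_het_probability(self, tmp_path):
        cfg = SimConfig(n_families=500, delta=0.4, f=0.0, r_mate=0.0, V_eps=0.5,
                        m_obs=200, m_lat=1, maf_range=(0.3, 0.5),
                        n_generations=1, seed=13)
        pops = simulate_population(cfg)
        paths = export_fixture(pops, out_dir=tmp_path)
        trios = pgsio.load_trio_genotypes(paths["vcf"], paths["pedigree"], phased=False)
        weights = pgsio.read_weight_table(paths["weights"])
        scores = pgsio.haplotypic_scores(trios, weights)
        # P(all three het) = (2pq)^2 * 1/2 per locus under random mating
        p = pops[0].variants.query("observed").maf.to_numpy()
        expect = ((2 * p * (1 - p)) ** 2 / 2).sum()
        observed = scores.n_ambiguous.mean()
        se = np.sqrt(expect / len(scores))  # Poisson-binomial scale bound
        assert observed == pytest.approx(expect, abs=4 * se + 0.05 * expect)


@pytest.mark.filterwarnings("ignore:.*ambiguous.*:RuntimeWarning")
@given(
    father=st.integers(0, 2), mother=st.integers(0, 2),
    w1=st.floats(-2, 2), w2=st.floats(-2, 2),
)
def test_split_policy_conserves_parent_score(father, mother, w1, w2):
    """T + NT equals the parent's full PGS exactly under the split policy."""
    offspring_opts = brute_force_transmissions(father, mother, 1)
    do = 1 if offspring_opts else father // 2 + mother // 2
    variants = pd.DataFrame({
        "chromosome": "1", "position": [1, 2], "ref": "A", "alt": "G",
        "variant_id": ["v1", "v2"],
    })
    trios = pgsio.TrioGenotypes(
        variants=variants, families=["f1"],
        father_dos=np.array([[father, father]], dtype=np.int8),
        mother_dos=np.array([[mother, mother]], dtype=np.int8),
        off_dos=np.array([[do, do]], dtype=np.int8),
        off_pat=None, off_mat=None, phased=False,
    )
    weights = pd.DataFrame({
        "variant_id": ["v1", "v2"], "chromosome": "1", "position": [1, 2],
        "effect_allele": "G", "other_allele": "A", "weight": [w1, w2],
    })
    scores = pgsio.haplotypic_scores(trios, weights, ambiguity_policy="split")
    if scores.n_mendelian_errors.iloc[0] == 0:
        full_father = (w1 + w2) * father
        assert scores.T_p.iloc[0] + scores.NT_p.iloc[0] == pytest.approx(full_father, abs=1e-12)


def test_all_homozygous_trio_forces_t_equal_nt():
    variants = pd.DataFrame({
        "chromosome": "1", "position": [1, 2], "ref": "A", "alt": "G",
        "variant_id": ["v1", "v2"],
    })
    trios = pgsio.TrioGenotypes(
        variants=variants, families=["f1"],
        father_dos=np.array([[2, 0]], dtype=np.int8),
        mother_dos=np.array([[2, 0]], dtype=np.int8),
        off_dos=np.array([[2, 0]], dtype=np.int8),
        off_pat=None, off_mat=None, phased=False,
    )
    weights = pd.DataFrame({
        "variant_id": ["v1", "v2"], "chromosome": "1", "position": [1, 2],
        "effect_allele": "G", "other_allele": "A", "weight": [1.0, 2.0],
    })
    scores = pgsio.haplotypic_scores(trios, weights)
    assert scores.T_p.iloc[0] == scores.NT_p.iloc[0] == 1.0  # weight-1 allele only


def test_allele_flip_handling():
    variants = pd.DataFrame({
        "chromosome": "1", "position": [1], "ref": "A", "alt": "G", "variant_id": ["v1"],
    })
    trios = pgsio.TrioGenotypes(
        variants=variants, families=["f1"],
        father_dos=np.array([[2]], dtype=np.int8),
        mother_dos=np.array([[0]], dtype=np.int8),
        off_dos=np.array([[1]], dtype=np.int8),
        off_pat=None, off_mat=None, phased=False,
    )
    # effect allele is REF: father is G/G so carries zero effect alleles
    weights = pd.DataFrame({
        "variant_id": ["v1"], "chromosome": "1", "position": [1],
        "effect_allele": "A", "other_allele": "G", "weight": [1.0],
    })
    scores = pgsio.haplotypic_scores(trios, weights)
    assert scores.T_p.iloc[0] == 0.0
    assert scores.T_m.iloc[0] == 1.0  # mother A/A transmits one effect allele


class TestStandardizeScores:
    def test_full_standardization_exact(self, am_m2_table):
        df, k = pgsio.standardize_scores(am_m2_table, "full_pgs_standardized_now")
        pooled = np.concatenate([df.T_p + df.NT_p, df.T_m + df.NT_m])
        assert pooled.var() == pytest.approx(1.0, rel=1e-6)
        assert 0 < k < 0.5

    def test_no_am_all_conventions_near_half(self, no_am_table):
        for conv in ("full_pgs_standardized_now", "haplotypic_half_now"):
            _, k = pgsio.standardize_scores(no_am_table, conv)
            assert k == pytest.approx(0.5, abs=0.02)

    def test_equilibrium_am_k_matches_analytic(self, am_m2_table):
        from pgsnurture import ModelParams, equilibrium_state
        from pgsnurture.params import Scaling

        _, k = pgsio.standardize_scores(am_m2_table, "full_pgs_standardized_now")
        st_full = equilibrium_state(
            ModelParams(delta=0.3, a=0.55, f=0.12, r_mate=0.3, V_eps=0.4,
                        scaling=Scaling.full_pgs_standardized_now),
            model="m2",
        )
        assert k == pytest.approx(st_full.k, abs=0.02)

    def test_base_requires_known_variance(self, am_m2_table):
        with pytest.raises(ValueError, match="base"):
            pgsio.standardize_scores(am_m2_table, "base_standardized")


def test_family_table_io_roundtrip(tmp_path, no_am_table):
    df = no_am_table.head(50).copy()
    df.loc[df.index[:10], "Y_p"] = np.nan
    path = tmp_path / "fam.tsv"
    pgsio.write_family_table(df, path)
    assert "NA" in path.read_text()
    back = pgsio.read_family_table(path)
    pd.testing.assert_frame_equal(back, df.reset_index(drop=True), atol=1e-9, check_dtype=False)
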
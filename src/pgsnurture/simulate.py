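"""Forward-time, variant-level simulation of assortative mating and VT.

The engine follows the classic family-simulation recipe: a base population
with causal variants in linkage equilibrium, then discrete generations of
(optionally assortative) mating, Mendelian transmission with free
recombination, vertical transmission ``F_o = f (Y_p + Y_m)``, and phenotype
assembly ``Y = delta (PGS_1 + PGS_2) + a (LGS_1 + LGS_2) + F + eps``.

Haplotype 1 of every individual is the paternally derived gamete and
haplotype 2 the maternally derived one, so the four haplotypic PGSs
(T_p, NT_p, T_m, NT_m) of an offspring are read off directly.

Per-locus effect sizes are drawn standard normal and rescaled so each
haplotypic score has variance exactly 1/2 in the realised base generation,
making the base constants k = j = 1/2 exact rather than estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_PATTERNS = ("complete", "phenotype_pairs", "pairs_only")

_COLUMNS = ["family_id", "T_p", "NT_p", "T_m", "NT_m", "Y_o", "Y_p", "Y_m"]


@dataclass
class SimConfig:
    """Study conditions for one simulated population.

    ``am_onset`` is the index of the first mating event at which spouses are
    matched assortatively; 0 means AM from the base generation onwards,
    ``n_generations - 1`` gives a single (most recent) generation of AM,
    the disequilibrium scenario.
    """

    n_families: int
    delta: float
    a: float = 0.0
    f: float = 0.0
    r_mate: float = 0.0
    V_eps: float = 1.0
    m_obs: int = 50
    m_lat: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_generations: int = 15
    seed: int = 0
    am_onset: int = 0
    store_haplotypes: bool = True

    def validate(self) -> None:
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        if self.m_obs < 1 or self.m_lat < 1:
            raise ValueError("m_obs and m_lat must be >= 1")
        if not 0 <= self.r_mate < 1:
            raise ValueError(f"r_mate must be in [0, 1), got {self.r_mate}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range bounds must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.V_eps <= 0:
            raise ValueError("V_eps must be positive")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")


@dataclass
class Population:
    """One generation of individuals.

    The first ``n_families`` individuals are male, the rest female; couple
    ``c`` of the next generation pairs one male with one female and produces
    exactly two offspring (one of each sex), keeping population size fixed.
    """

    generation: int
    pgs_hap: np.ndarray            # (n, 2) haplotypic PGS, [:, 0] paternal gamete
    lgs_hap: np.ndarray            # (n, 2) haplotypic LGS
    phenotype: np.ndarray          # (n,)
    F: np.ndarray                  # (n,) familial environment score
    father: np.ndarray | None      # (n,) index into previous generation
    mother: np.ndarray | None
    nt_pgs_p: np.ndarray | None    # father's nontransmitted haplotypic PGS
    nt_pgs_m: np.ndarray | None
    nt_lgs_p: np.ndarray | None
    nt_lgs_m: np.ndarray | None
    haplotypes: np.ndarray | None  # (n, 2, m_obs + m_lat) int8, or None
    variants: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.phenotype)


def assort_mates(
    y_males: np.ndarray,
    y_females: np.ndarray,
    r_mate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair males with females so spousal phenotypes correlate ~ r_mate.

    Uses a Gaussian copula on phenotype ranks: a bivariate normal sample
    with correlation ``r_mate`` supplies the target joint rank structure,
    and individuals are matched to it by phenotype rank.  Each individual is
    used exactly once, and the realised Pearson correlation equals the
    target in expectation (up to the normality of the phenotype margins).
    """
    nf = len(y_males)
    if len(y_females) != nf:
        raise ValueError("need equal numbers of males and females")
    if r_mate == 0.0:
        return rng.permutation(nf), rng.permutation(nf)
    z1 = rng.standard_normal(nf)
    z2 = r_mate * z1 + np.sqrt(1.0 - r_mate**2) * rng.standard_normal(nf)
    m_by_rank = np.argsort(y_males, kind="stable")
    f_by_rank = np.argsort(y_females, kind="stable")
    fathers = m_by_rank[np.argsort(np.argsort(z1))]
    mothers = f_by_rank[np.argsort(np.argsort(z2))]
    realized = np.corrcoef(y_males[fathers], y_females[mothers])[0, 1]
    if nf >= 1000 and abs(realized - r_mate) > max(0.01, 4.0 / np.sqrt(nf)):
        warnings.warn(
            f"realized spousal correlation {realized:.4f} deviates from target {r_mate:.4f}",
            RuntimeWarning,
        )
    return fathers, mothers


def transmit(haplotypes: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fair Mendelian transmission with free recombination.

    For each parent (rows of ``haplotypes`` with shape (n, 2, m)) and each
    locus independently, one of the two alleles is transmitted with
    probability 1/2; the nontransmitted gamete is the locus-wise complement.
    """
    n, _, m = haplotypes.shape
    choice = rng.integers(0, 2, size=(n, m)).astype(bool)
    transmitted = np.where(choice, haplotypes[:, 1, :], haplotypes[:, 0, :])
    nontransmitted = np.where(choice, haplotypes[:, 0, :], haplotypes[:, 1, :])
    return transmitted, nontransmitted


def _scores(gametes: np.ndarray, beta_obs: np.ndarray, beta_lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m_obs = len(beta_obs)
    pgs = gametes[:, :m_obs].astype(np.float64) @ beta_obs
    lgs = gametes[:, m_obs:].astype(np.float64) @ beta_lat
    return pgs, lgs


def simulate_population(config: SimConfig) -> list[Population]:
    """Run the forward simulation, returning one Population per generation."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nf = config.n_families
    n_ind = 2 * nf
    m_obs, m_lat = config.m_obs, config.m_lat
    m = m_obs + m_lat

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    beta = rng.standard_normal(m)
    hap0 = (rng.random((n_ind, 2, m)) < maf).astype(np.int8)

    # rescale effects so each realised base-generation haplotypic score
    # variance is exactly 1/2 (k = j = 1/2 exact)
    beta_obs, beta_lat = beta[:m_obs].copy(), beta[m_obs:].copy()
    for sl, b in ((slice(0, m_obs), beta_obs), (slice(m_obs, m), beta_lat)):
        hap_scores = hap0[:, :, sl].reshape(2 * n_ind, -1).astype(np.float64) @ b
        sd = hap_scores.std()
        if sd == 0:
            raise ValueError("degenerate base population: zero haplotypic score variance")
        b *= np.sqrt(0.5) / sd

    variants = pd.DataFrame(
        {
            "variant_id": [f"var{l}" for l in range(m)],
            "chromosome": "1",
            "position": np.arange(1, m + 1),
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "weight": np.concatenate([beta_obs, beta_lat]),
            "observed": [True] * m_obs + [False] * m_lat,
        }
    )

    pgs0, lgs0 = _scores(hap0.reshape(n_ind * 2, m), beta_obs, beta_lat)
    pgs_hap = pgs0.reshape(n_ind, 2)
    lgs_hap = lgs0.reshape(n_ind, 2)
    F0 = np.zeros(n_ind)
    eps = rng.normal(0.0, np.sqrt(config.V_eps), n_ind)
    Y0 = config.delta * pgs_hap.sum(1) + config.a * lgs_hap.sum(1) + F0 + eps

    pops = [
        Population(
            generation=0, pgs_hap=pgs_hap, lgs_hap=lgs_hap, phenotype=Y0, F=F0,
            father=None, mother=None, nt_pgs_p=None, nt_pgs_m=None,
            nt_lgs_p=None, nt_lgs_m=None,
            haplotypes=hap0 if config.store_haplotypes else None,
            variants=variants,
        )
    ]

    haps = hap0
    for t in range(config.n_generations):
        prev = pops[-1]
        y = prev.phenotype
        r = config.r_mate if t >= config.am_onset else 0.0
        fathers_loc, mothers_loc = assort_mates(y[:nf], y[nf:], r, rng)
        fathers = fathers_loc                  # global index: males are 0..nf-1
        mothers = nf + mothers_loc

        f_hap = haps[fathers]
        m_hap = haps[mothers]
        f_pgs_tot = prev.pgs_hap[fathers].sum(1)
        m_pgs_tot = prev.pgs_hap[mothers].sum(1)
        f_lgs_tot = prev.lgs_hap[fathers].sum(1)
        m_lgs_tot = prev.lgs_hap[mothers].sum(1)
        y_f, y_m = y[fathers], y[mothers]

        new_hap = np.empty((n_ind, 2, m), dtype=np.int8)
        pgs_hap = np.empty((n_ind, 2))
        lgs_hap = np.empty((n_ind, 2))
        nt_pgs_p = np.empty(n_ind)
        nt_pgs_m = np.empty(n_ind)
        nt_lgs_p = np.empty(n_ind)
        nt_lgs_m = np.empty(n_ind)

        # two offspring per couple: child 0 (male) at rows 0..nf-1, child 1
        # (female) at rows nf..2nf-1
        for child in range(2):
            rows = slice(child * nf, (child + 1) * nf)
            pat, _ = transmit(f_hap, rng)
            mat, _ = transmit(m_hap, rng)
            new_hap[rows, 0, :] = pat
            new_hap[rows, 1, :] = mat
            p_pgs, p_lgs = _scores(pat, beta_obs, beta_lat)
            m_pgs, m_lgs = _scores(mat, beta_obs, beta_lat)
            pgs_hap[rows, 0], pgs_hap[rows, 1] = p_pgs, m_pgs
            lgs_hap[rows, 0], lgs_hap[rows, 1] = p_lgs, m_lgs
            nt_pgs_p[rows] = f_pgs_tot - p_pgs
            nt_pgs_m[rows] = m_pgs_tot - m_pgs
            nt_lgs_p[rows] = f_lgs_tot - p_lgs
            nt_lgs_m[rows] = m_lgs_tot - m_lgs

        father_idx = np.tile(fathers, 2)
        mother_idx = np.tile(mothers, 2)
        F = config.f * (np.tile(y_f, 2) + np.tile(y_m, 2))
        eps = rng.normal(0.0, np.sqrt(config.V_eps), n_ind)
        Y = config.delta * pgs_hap.sum(1) + config.a * lgs_hap.sum(1) + F + eps

        pops.append(
            Population(
                generation=t + 1, pgs_hap=pgs_hap, lgs_hap=lgs_hap,
                phenotype=Y, F=F, father=father_idx, mother=mother_idx,
                nt_pgs_p=nt_pgs_p, nt_pgs_m=nt_pgs_m,
                nt_lgs_p=nt_lgs_p, nt_lgs_m=nt_lgs_m,
                haplotypes=new_hap if config.store_haplotypes else None,
                variants=variants,
            )
        )
        haps = new_hap
    return pops


def _apply_missingness(df: pd.DataFrame, pattern, rng: np.random.Generator) -> pd.DataFrame:
    """Mask values completely at random according to the requested pattern."""
    df = df.copy()
    cols = [c for c in _COLUMNS if c != "family_id"]
    if pattern in (None, "complete"):
        return df
    if pattern == "phenotype_pairs":
        pairs = [("Y_o", "Y_p"), ("Y_o", "Y_m"), ("Y_p", "Y_m")]
        which = rng.integers(0, 3, size=len(df))
        for idx, pair in enumerate(pairs):
            drop = [c for c in ("Y_o", "Y_p", "Y_m") if c not in pair]
            df.loc[which == idx, drop] = np.nan
        return df
    if pattern == "pairs_only":
        pairs = [(x, y) for xi, x in enumerate(cols) for y in cols[xi + 1:]]
        which = rng.integers(0, len(pairs), size=len(df))
        for idx, pair in enumerate(pairs):
            drop = [c for c in cols if c not in pair]
            df.loc[which == idx, drop] = np.nan
        return df
    if isinstance(pattern, dict):
        for col, prob in pattern.items():
            mask = rng.random(len(df)) < prob
            df.loc[mask, col] = np.nan
        return df
    raise ValueError(f"unknown missing_pattern {pattern!r}")


def extract_family_table(
    pops: list[Population],
    generation: int = -1,
    scaling: str = "base_standardized",
    missing_pattern=None,
    seed: int | None = None,
    n_sample: int | None = None,
) -> pd.DataFrame:
    """Per-family table (T_p, NT_p, T_m, NT_m, Y_o, Y_p, Y_m) at a generation.

    Uses the first offspring of each couple.  The haplotypic PGSs are
    computed over the observed loci only.  The scaling convention is applied
    to the four scores and the matching base constant ``k`` is recorded in
    ``df.attrs["k"]`` (exact, because the simulator knows the base-generation
    variance).

    ``n_sample`` draws that many families at random (seeded), emulating a
    study sample from a larger population; with the full population as the
    sample, families share the finite causal-locus panel and pedigree, which
    induces cross-family dependence a family-level bootstrap cannot see.
    """
    pop = pops[generation]
    if pop.generation < 1:
        raise ValueError("family tables require generation >= 1 (offspring need parents)")
    prev = pops[pop.generation - 1]
    nf = pop.n // 2

    df = pd.DataFrame(
        {
            "family_id": np.arange(nf),
            "T_p": pop.pgs_hap[:nf, 0],
            "NT_p": pop.nt_pgs_p[:nf],
            "T_m": pop.pgs_hap[:nf, 1],
            "NT_m": pop.nt_pgs_m[:nf],
            "Y_o": pop.phenotype[:nf],
            "Y_p": prev.phenotype[pop.father[:nf]],
            "Y_m": prev.phenotype[pop.mother[:nf]],
        }
    )[_COLUMNS]

    score_cols = ["T_p", "NT_p", "T_m", "NT_m"]
    from .params import Scaling, as_scaling

    s = as_scaling(scaling)
    if s is Scaling.base_standardized:
        k = 0.5
    elif s is Scaling.full_pgs_standardized_now:
        full = np.concatenate([df.T_p + df.NT_p, df.T_m + df.NT_m])
        s2 = full.var()
        df[score_cols] = df[score_cols] / np.sqrt(s2)
        k = 0.5 / s2
    else:
        hap = df[score_cols].to_numpy().ravel()
        s2h = hap.var()
        df[score_cols] = df[score_cols] * np.sqrt(0.5 / s2h)
        k = 0.25 / s2h
    if k <= 0:
        raise ValueError(f"scaling {scaling!r} yields k={k} <= 0")

    rng = np.random.default_rng(seed)
    if n_sample is not None:
        if n_sample > nf:
            raise ValueError(f"n_sample={n_sample} exceeds {nf} available families")
        df = df.iloc[np.sort(rng.choice(nf, size=n_sample, replace=False))].reset_index(drop=True)
    df = _apply_missingness(df, missing_pattern, rng)
    df.attrs["k"] = k
    df.attrs["scaling"] = s.value
    return df


def moment_trajectory(pops: list[Population]) -> pd.DataFrame:
    """Realised summary moments per generation (V_Y, g-hat, spousal cov...)."""
    rows = []
    for pop in pops:
        row = {"generation": pop.generation, "V_Y": pop.phenotype.var()}
        if pop.generation >= 1:
            nf = pop.n // 2
            T_p, T_m = pop.pgs_hap[:nf, 0], pop.pgs_hap[:nf, 1]
            NT_p, NT_m = pop.nt_pgs_p[:nf], pop.nt_pgs_m[:nf]
            row["g_cis"] = 0.5 * (np.cov(T_p, NT_p)[0, 1] + np.cov(T_m, NT_m)[0, 1])
            row["g_trans"] = np.cov(T_p, T_m)[0, 1]
            row["var_hap_pgs"] = np.concatenate([T_p, NT_p, T_m, NT_m]).var()
        rows.append(row)
    return pd.DataFrame(rows)


def plot_trajectory(pops: list[Population], ax=None):
    """Plot the approach of V_Y and the AM-induced covariances to equilibrium."""
    import matplotlib.pyplot as plt

    traj = moment_trajectory(pops)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.generation, traj.V_Y, marker="o", label="V_Y")
    if "g_cis" in traj:
        ax.plot(traj.generation, traj.g_cis, marker="s", label="cis g")
        ax.plot(traj.generation, traj.g_trans, marker="^", label="trans g")
    ax.set_xlabel("generation")
    ax.legend()
    return ax


def write_family_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def export_fixture(
    pops: list[Population],
    generation: int = -1,
    out_dir="fixture",
    prefix: str = "trios",
) -> dict[str, Path]:
    """Write a phased trio VCF, a PGS weight table, phenotypes and a pedigree.

    Offspring genotypes are phased paternal|maternal.  Only observed loci go
    into the VCF/weights, so scoring the fixture with :mod:`pgsnurture.pgsio`
    reproduces the simulator-internal T/NT values exactly.
    """
    pop = pops[generation]
    if pop.haplotypes is None:
        raise ValueError("export requires store_haplotypes=True in SimConfig")
    prev = pops[pop.generation - 1]
    if prev.haplotypes is None:
        raise ValueError("export requires parental haplotypes; store_haplotypes=True")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / f"{prefix}.vcf",
        "weights": out / f"{prefix}.weights.tsv",
        "phenotypes": out / f"{prefix}.phenotypes.tsv",
        "pedigree": out / f"{prefix}.ped.tsv",
    }

    nf = pop.n // 2
    var = pop.variants[pop.variants.observed].reset_index(drop=True)
    m_obs = len(var)
    fathers, mothers = pop.father[:nf], pop.mother[:nf]

    sample_ids, hap_list = [], []
    for fam in range(nf):
        sample_ids += [f"fam{fam}_p", f"fam{fam}_m", f"fam{fam}_o"]
        hap_list += [prev.haplotypes[fathers[fam], :, :m_obs],
                     prev.haplotypes[mothers[fam], :, :m_obs],
                     pop.haplotypes[fam, :, :m_obs]]
    H = np.stack(hap_list)  # (n_samples, 2, m_obs)

    try:
        with open(paths["vcf"], "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=pgsnurture-simulate\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
            gt = np.char.add(np.char.add(H[:, 0, :].astype("U1"), "|"), H[:, 1, :].astype("U1"))
            for l in range(m_obs):
                rec = var.iloc[l]
                fields = [str(rec.chromosome), str(rec.position), rec.variant_id,
                          rec.ref, rec.alt, ".", "PASS", ".", "GT"]
                fh.write("\t".join(fields) + "\t" + "\t".join(gt[:, l]) + "\n")

        var[["variant_id", "chromosome", "position"]].assign(
            effect_allele=var.alt, other_allele=var.ref, weight=var.weight
        ).to_csv(paths["weights"], sep="\t", index=False, float_format="%.12g")

        phen = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "phenotype": np.concatenate(
                    [
                        np.column_stack(
                            [prev.phenotype[fathers], prev.phenotype[mothers], pop.phenotype[:nf]]
                        ).ravel()
                    ]
                ),
            }
        )
        phen.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.10g")

        pd.DataFrame(
            {
                "family_id": np.arange(nf),
                "father_id": [f"fam{i}_p" for i in range(nf)],
                "mother_id": [f"fam{i}_m" for i in range(nf)],
                "offspring_id": [f"fam{i}_o" for i in range(nf)],
            }
        ).to_csv(paths["pedigree"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out}: {exc}") from exc
    return paths
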
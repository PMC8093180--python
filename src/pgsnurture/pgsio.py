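"""Construct haplotypic PGSs (T_p, NT_p, T_m, NT_m) from trio genotypes.

Phased trio data (offspring haplotype 1 = paternal by convention,
configurable upstream) identify each parent's transmitted allele directly;
for unphased data transmission is deduced by Mendelian logic, which fails
only when father, mother and offspring are all heterozygous (the ambiguous
triple-het configuration).  Ambiguous sites either contribute half the
parental genotype score to both T and NT (``split``, unbiased for the score
sums) or are dropped for that family (``drop``).

Weight-table alleles are matched to VCF REF/ALT by allele identity only (no
strand inference); sites whose alleles do not match are dropped and counted.
Multi-allelic and missing-genotype sites are likewise excluded and counted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .amtest import solve_gk, raw_score_moments
from .params import Scaling, as_scaling

SCORE_COLS = ["T_p", "NT_p", "T_m", "NT_m"]

WEIGHT_COLUMNS = ["variant_id", "chromosome", "position", "effect_allele", "other_allele", "weight"]


class Transmission(Enum):
    AMBIGUOUS = "AMBIGUOUS"
    MENDELIAN_ERROR = "MENDELIAN_ERROR"


AMBIGUOUS = Transmission.AMBIGUOUS
MENDELIAN_ERROR = Transmission.MENDELIAN_ERROR


def read_weight_table(path) -> pd.DataFrame:
    """Read a PGS scoring file (TSV with the WeightTable columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weight table {path} lacks columns {missing}")
    if df.variant_id.duplicated().any():
        raise ValueError("weight table has duplicated variant_ids")
    if (df.effect_allele == df.other_allele).any():
        raise ValueError("weight table has identical effect and other alleles")
    if not np.isfinite(df.weight).all():
        raise ValueError("weight table has non-finite weights")
    return df


def read_family_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_family_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


@dataclass
class TrioGenotypes:
    """Genotype calls of father/mother/offspring over shared biallelic sites."""

    variants: pd.DataFrame        # chromosome, position, ref, alt, variant_id
    families: list
    father_dos: np.ndarray        # (n_fam, n_var) int8 dosage, -1 = missing
    mother_dos: np.ndarray
    off_dos: np.ndarray
    off_pat: np.ndarray | None    # offspring paternal-haplotype allele (phased)
    off_mat: np.ndarray | None
    phased: bool
    n_multiallelic: int = 0

    @property
    def n_families(self) -> int:
        return len(self.families)


def load_trio_genotypes(vcf_path, pedigree, phased: bool | None = None) -> TrioGenotypes:
    """Load trios from a VCF and a pedigree (TSV path or DataFrame).

    ``phased=None`` auto-detects from the offspring genotype separators.
    Offspring haplotype 1 is taken as paternal (trio-phased convention).
    """
    from cyvcf2 import VCF

    ped = pedigree if isinstance(pedigree, pd.DataFrame) else pd.read_csv(pedigree, sep="\t")
    for c in ("family_id", "father_id", "mother_id", "offspring_id"):
        if c not in ped.columns:
            raise ValueError(f"pedigree lacks column {c!r}")

    vcf = VCF(str(vcf_path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    for c in ("father_id", "mother_id", "offspring_id"):
        absent = [s for s in ped[c] if s not in sample_idx]
        if absent:
            raise ValueError(f"samples missing from VCF: {absent[:5]}...")
    fi = ped.father_id.map(sample_idx).to_numpy()
    mi = ped.mother_id.map(sample_idx).to_numpy()
    oi = ped.offspring_id.map(sample_idx).to_numpy()

    rows, fd, md, od, op, om = [], [], [], [], [], []
    phased_calls = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.genotypes, dtype=np.int16)  # (n_samples, 3): a0, a1, phased
        a0, a1 = gt[:, 0].astype(np.int8), gt[:, 1].astype(np.int8)
        dos = np.where((a0 >= 0) & (a1 >= 0), a0 + a1, -1).astype(np.int8)
        rows.append((str(v.CHROM), int(v.POS), v.REF, v.ALT[0], v.ID or f"{v.CHROM}:{v.POS}"))
        fd.append(dos[fi]); md.append(dos[mi]); od.append(dos[oi])
        op.append(a0[oi]); om.append(a1[oi])
        phased_calls.append(bool(gt[oi, 2].all()))
    if not rows:
        raise ValueError(f"no biallelic variants in {vcf_path}")

    variants = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt", "variant_id"])
    if phased is None:
        phased = all(phased_calls)
    return TrioGenotypes(
        variants=variants, families=list(ped.family_id),
        father_dos=np.array(fd).T, mother_dos=np.array(md).T, off_dos=np.array(od).T,
        off_pat=np.array(op).T if phased else None,
        off_mat=np.array(om).T if phased else None,
        phased=phased, n_multiallelic=n_multi,
    )


def _alleles(dosage: int) -> set:
    return {0} if dosage == 0 else ({1} if dosage == 2 else {0, 1})


def resolve_transmission(father: int, mother: int, offspring, phased: bool = False):
    """Transmitted alleles (t_p, t_m) for one biallelic site, or a sentinel.

    ``offspring`` is the dosage (unphased) or the (paternal, maternal)
    allele pair (phased).  Returns ``AMBIGUOUS`` when both assignments are
    Mendelian-consistent (all three heterozygous, unphased only) and
    ``MENDELIAN_ERROR`` when none is.
    """
    if phased:
        t_p, t_m = offspring
        if t_p not in _alleles(father) or t_m not in _alleles(mother):
            return MENDELIAN_ERROR
        return (int(t_p), int(t_m))
    options = sorted(
        {(tp, offspring - tp) for tp in _alleles(father) if (offspring - tp) in _alleles(mother)}
    )
    if not options:
        return MENDELIAN_ERROR
    if len(options) > 1:
        return AMBIGUOUS
    return options[0]


def _align_weights(variants: pd.DataFrame, weights: pd.DataFrame):
    """Match VCF sites to weight rows by position and allele identity."""
    w = weights.copy()
    w["position"] = w.position.astype(int)
    merged = variants.reset_index(names="vcf_idx").merge(
        w, on=["chromosome", "position"], how="inner", suffixes=("", "_w")
    )
    direct = (merged.effect_allele == merged.alt) & (merged.other_allele == merged.ref)
    flipped = (merged.effect_allele == merged.ref) & (merged.other_allele == merged.alt)
    n_mismatch = int((~(direct | flipped)).sum())
    merged = merged[direct | flipped]
    return (
        merged.vcf_idx.to_numpy(),
        merged.weight.to_numpy(float),
        flipped[direct | flipped].to_numpy(),
        n_mismatch,
    )


def haplotypic_scores(
    trios: TrioGenotypes,
    weights: pd.DataFrame,
    ambiguity_policy: str = "split",
) -> pd.DataFrame:
    """Per-family haplotypic PGSs with transmission bookkeeping.

    Returns a DataFrame with T_p, NT_p, T_m, NT_m plus per-family counts of
    used, ambiguous and Mendelian-error sites.  QC totals are stored in
    ``df.attrs["qc"]``.
    """
    if ambiguity_policy not in ("split", "drop"):
        raise ValueError("ambiguity_policy must be 'split' or 'drop'")
    idx, w, flip, n_mismatch = _align_weights(trios.variants, weights)
    if len(idx) == 0:
        raise ValueError("no overlapping variants between trios and weight table")

    Gf = trios.father_dos[:, idx].astype(float)
    Gm = trios.mother_dos[:, idx].astype(float)
    Go = trios.off_dos[:, idx].astype(float)
    missing = (Gf < 0) | (Gm < 0) | (Go < 0)

    if trios.phased:
        tp = trios.off_pat[:, idx].astype(float)
        tm = trios.off_mat[:, idx].astype(float)
        mend = ((tp == 1) & (Gf == 0)) | ((tp == 0) & (Gf == 2)) \
             | ((tm == 1) & (Gm == 0)) | ((tm == 0) & (Gm == 2))
        amb = np.zeros_like(mend)
    else:
        valid10 = (Gf >= 1) & (Gm <= 1)   # (t_p, t_m) = (1, 0)
        valid01 = (Gf <= 1) & (Gm >= 1)   # (t_p, t_m) = (0, 1)
        tp = np.full(Gf.shape, np.nan)
        tm = np.full(Gf.shape, np.nan)
        is0, is1, is2 = Go == 0, Go == 1, Go == 2
        ok0 = is0 & (Gf <= 1) & (Gm <= 1)
        ok2 = is2 & (Gf >= 1) & (Gm >= 1)
        tp[ok0], tm[ok0] = 0, 0
        tp[ok2], tm[ok2] = 1, 1
        amb = is1 & valid10 & valid01
        only10 = is1 & valid10 & ~valid01
        only01 = is1 & ~valid10 & valid01
        tp[only10], tm[only10] = 1, 0
        tp[only01], tm[only01] = 0, 1
        mend = (is0 & ~ok0) | (is2 & ~ok2) | (is1 & ~valid10 & ~valid01)

    mend = mend & ~missing
    amb = amb & ~missing
    resolved = ~missing & ~mend & ~amb
    use_amb = amb if ambiguity_policy == "split" else np.zeros_like(amb)

    # allele-flip handling: count effect alleles, not ALT alleles
    tp_eff = np.where(flip, 1.0 - tp, tp)
    tm_eff = np.where(flip, 1.0 - tm, tm)
    Gf_eff = np.where(flip, 2.0 - Gf, Gf)
    Gm_eff = np.where(flip, 2.0 - Gm, Gm)

    T_p = (np.where(resolved, tp_eff, 0.0) * w).sum(axis=1) \
        + 0.5 * (np.where(use_amb, Gf_eff, 0.0) * w).sum(axis=1)
    NT_p = (np.where(resolved, Gf_eff - tp_eff, 0.0) * w).sum(axis=1) \
        + 0.5 * (np.where(use_amb, Gf_eff, 0.0) * w).sum(axis=1)
    T_m = (np.where(resolved, tm_eff, 0.0) * w).sum(axis=1) \
        + 0.5 * (np.where(use_amb, Gm_eff, 0.0) * w).sum(axis=1)
    NT_m = (np.where(resolved, Gm_eff - tm_eff, 0.0) * w).sum(axis=1) \
        + 0.5 * (np.where(use_amb, Gm_eff, 0.0) * w).sum(axis=1)

    n_used = (resolved | use_amb).sum(axis=1)
    n_amb = amb.sum(axis=1)
    n_mend = mend.sum(axis=1)

    if not trios.phased:
        amb_rate = amb[~missing & ~mend].mean() if (~missing & ~mend).any() else 0.0
        if amb_rate > 0.2:
            warnings.warn(
                f"{amb_rate:.1%} of resolvable sites are ambiguous (triple heterozygous) "
                "under unphased Mendelian deduction",
                RuntimeWarning,
            )

    df = pd.DataFrame(
        {
            "family_id": trios.families,
            "T_p": T_p, "NT_p": NT_p, "T_m": T_m, "NT_m": NT_m,
            "n_sites_used": n_used, "n_ambiguous": n_amb, "n_mendelian_errors": n_mend,
        }
    )
    df.attrs["qc"] = {
        "n_sites_matched": int(len(idx)),
        "n_allele_mismatch": int(n_mismatch),
        "n_multiallelic": int(trios.n_multiallelic),
        "n_missing_calls": int(missing.sum()),
        "n_ambiguous": int(amb.sum()),
        "n_mendelian_errors": int(mend.sum()),
        "ambiguity_policy": ambiguity_policy,
        "phased": trios.phased,
    }
    return df


def standardize_scores(
    table: pd.DataFrame,
    convention="full_pgs_standardized_now",
    base_hap_variance: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Apply a scaling convention to the four haplotypic scores.

    Returns the rescaled table and the base constant ``k`` the estimator
    must use.  For the current-generation conventions, the AM-induced
    covariance g-hat needed by the ``k`` formula comes from the joint
    consistency solve over the six cis moment estimates (see
    :func:`pgsnurture.amtest.solve_gk`).
    """
    if len(table.dropna(subset=SCORE_COLS)) < 2:
        raise ValueError("need at least 2 families with complete scores")
    s = as_scaling(convention)
    df = table.copy()
    if s is Scaling.base_standardized:
        if base_hap_variance is None:
            raise ValueError(
                "base_standardized requires the base-generation haplotypic variance "
                "(unknowable from current-generation data alone)"
            )
        factor = np.sqrt(0.5 / base_hap_variance)
        df[SCORE_COLS] = df[SCORE_COLS] * factor
        k = 0.5
    elif s is Scaling.full_pgs_standardized_now:
        full = np.concatenate([
            (df.T_p + df.NT_p).dropna().to_numpy(),
            (df.T_m + df.NT_m).dropna().to_numpy(),
        ])
        df[SCORE_COLS] = df[SCORE_COLS] / full.std()
        _, k = solve_gk(raw_score_moments(df.dropna(subset=SCORE_COLS)), s)
    else:
        hap = df[SCORE_COLS].to_numpy(float)
        pooled_var = np.nanvar(hap)
        df[SCORE_COLS] = df[SCORE_COLS] * np.sqrt(0.5 / pooled_var)
        _, k = solve_gk(raw_score_moments(df.dropna(subset=SCORE_COLS)), s)
    if k <= 0:
        raise ValueError(f"convention {s.value!r} implies k={k:.4g} <= 0 (AM too strong)")
    return df, k


def build_family_table(
    scores: pd.DataFrame,
    pedigree: pd.DataFrame,
    phenotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join haplotypic scores with phenotypes into the estimator layout."""
    df = scores.merge(pedigree, on="family_id", how="left")
    for col in ("Y_o", "Y_p", "Y_m"):
        df[col] = np.nan
    if phenotypes is not None:
        pmap = phenotypes.set_index("sample_id").phenotype
        df["Y_o"] = df.offspring_id.map(pmap)
        df["Y_p"] = df.father_id.map(pmap)
        df["Y_m"] = df.mother_id.map(pmap)
    return df[["family_id", "T_p", "NT_p", "T_m", "NT_m", "Y_o", "Y_p", "Y_m"]]


def write_qc_json(scores: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(scores.attrs.get("qc", {}), fh, indent=2)
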
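"""Headline genetic quantities for the pure lines and the F1 cross.

Converts estimated per-SNP variances and observed parental allele
frequencies into population-level genetic variances via the multi-locus
formulas, and derives the quantities a breeder reads off such an
analysis: the F1 additive (GCA) and dominance (SCA) variances, the
dominance share of the F1 total genetic variance, within-line
narrow-sense heritabilities, and inbreeding depression scaled per 10 %
increase in genomic homozygosity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .locus import multilocus_f1_variances, pureline_variances
from .reml import ComponentEstimates, SNPVariances

__all__ = ["F1VarianceReport", "build_report", "scale_inbreeding_depression",
           "dominance_fraction"]


@dataclass
class F1VarianceReport:
    """Derived genetic variances and ratios (trait units^2 / unitless).

    ``var_A1_cross``/``var_A2_cross`` are the gametic (GCA) variances of
    the two lines within the F1, ``var_D_cross`` the SCA variance, and
    ``dominance_fraction_of_total`` = var_D / (var_A + var_D) with its
    integer-percent headline rounding in ``dominance_pct_headline``.
    """

    populations: list
    var_A1_cross: float
    var_A2_cross: float
    var_A_cross: float
    var_D_cross: float
    se_var_A1_cross: float
    se_var_A2_cross: float
    se_var_D_cross: float
    var_A_pure: dict
    var_D_pure: dict
    narrow_sense_h2: dict
    dominance_fraction_of_total: float
    dominance_to_additive_ratio: float
    dominance_pct_headline: int
    inbreeding_depression_per_10pct: dict

    def to_json(self, path=None):
        payload = asdict(self)
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_markdown(self) -> str:
        lines = [
            "# F1 variance report",
            "",
            "| quantity | value |",
            "|---|---|",
            f"| gametic (GCA) variance, line 1 alleles | {self.var_A1_cross:.4g} |",
            f"| gametic (GCA) variance, line 2 alleles | {self.var_A2_cross:.4g} |",
            f"| F1 additive variance | {self.var_A_cross:.4g} |",
            f"| F1 dominance (SCA) variance | {self.var_D_cross:.4g} |",
            f"| dominance share of F1 genetic variance | "
            f"{100 * self.dominance_fraction_of_total:.1f} % "
            f"(~{self.dominance_pct_headline} %) |",
        ]
        for pop, h2 in self.narrow_sense_h2.items():
            lines.append(f"| narrow-sense h2, {pop} | {h2:.3f} |")
        for pop, dep in self.inbreeding_depression_per_10pct.items():
            lines.append(f"| inbreeding depression per +10 % F_Ho, {pop} | {dep:.2f} |")
        return "\n".join(lines)


def scale_inbreeding_depression(coefficient_per_unit_fho: float, delta: float) -> float:
    """Change in phenotypic mean for an increase of ``delta`` in F_Ho
    (e.g. delta = 0.10 for a 10 % increase in homozygosity)."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    return coefficient_per_unit_fho * delta


def build_report(
    snp_vars: SNPVariances,
    freqs: pd.DataFrame,
    est: ComponentEstimates | None = None,
    line1=None,
    line2=None,
    f1=None,
) -> F1VarianceReport:
    """Assemble the variance report from SNP variances and parental
    allele frequencies (observed, post-QC, in the parental lines).

    ``freqs`` is the populations x markers table of
    :func:`crossblup.genotypes.allele_freqs`.  The F1 population's SNP
    variances enter the cross formulas; each line's own SNP variances
    enter its within-line formulas.  If ``est`` is given, heritabilities
    and the F_Ho regression coefficients (scaled per 10 % homozygosity)
    are included, and SEs of the cross variances follow by the delta
    method (linearity in the SNP variances).
    """
    pops = list(snp_vars.populations)
    line1 = pops[0] if line1 is None else line1
    line2 = pops[1] if line2 is None else line2
    f1 = pops[2] if f1 is None else f1
    i1, i2, i12 = pops.index(line1), pops.index(line2), pops.index(f1)

    p = freqs.loc[line1].to_numpy(float)
    pp = freqs.loc[line2].to_numpy(float)
    bad = np.isnan(p) | np.isnan(pp)
    if bad.any():
        raise ValueError(
            "missing parental allele frequency for markers: "
            f"{list(freqs.columns[bad][:10])}"
        )

    cross = multilocus_f1_variances(p, pp, snp_vars.sigma2_a[i12],
                                    snp_vars.sigma2_d[i12])
    q, qp = 1 - p, 1 - pp
    # linear coefficients of the cross variances in (sigma2_a12, sigma2_d12)
    cA1 = (float(np.sum(2 * p * q)), float(np.sum(2 * p * q * (qp - pp) ** 2)))
    cA2 = (float(np.sum(2 * pp * qp)), float(np.sum(2 * pp * qp * (q - p) ** 2)))
    cD = float(np.sum(4 * p * q * pp * qp))
    se_a12 = snp_vars.se_sigma2_a[i12]
    se_d12 = snp_vars.se_sigma2_d[i12]
    se_A1 = float(np.hypot(cA1[0] * se_a12, cA1[1] * se_d12))
    se_A2 = float(np.hypot(cA2[0] * se_a12, cA2[1] * se_d12))
    se_D = float(cD * se_d12)

    var_A_pure, var_D_pure, h2 = {}, {}, {}
    for pop, idx in ((line1, i1), (line2, i2)):
        vA, vD = pureline_variances(
            freqs.loc[pop].to_numpy(float), snp_vars.sigma2_a[idx],
            snp_vars.sigma2_d[idx])
        var_A_pure[pop] = vA
        var_D_pure[pop] = vD
        if est is not None:
            tot = vA + vD + est.perm_env[idx] + est.residual[idx]
            h2[pop] = vA / tot if tot > 0 else float("nan")

    depression = {}
    if est is not None:
        for pop in (line1, line2, f1):
            name = f"F_Ho:{pop}"
            if name in est.fixed_names:
                coef = float(est.beta[est.fixed_names.index(name)])
                depression[pop] = scale_inbreeding_depression(coef, 0.10)

    total = cross.var_A + cross.var_D
    frac = cross.var_D / total if total > 0 else 0.0
    ratio = cross.var_D / cross.var_A if cross.var_A > 0 else float("inf")
    return F1VarianceReport(
        populations=[line1, line2, f1],
        var_A1_cross=cross.var_A1,
        var_A2_cross=cross.var_A2,
        var_A_cross=cross.var_A,
        var_D_cross=cross.var_D,
        se_var_A1_cross=se_A1,
        se_var_A2_cross=se_A2,
        se_var_D_cross=se_D,
        var_A_pure=var_A_pure,
        var_D_pure=var_D_pure,
        narrow_sense_h2=h2,
        dominance_fraction_of_total=frac,
        dominance_to_additive_ratio=ratio,
        dominance_pct_headline=int(round(100 * frac)),
        inbreeding_depression_per_10pct=depression,
    )


def dominance_fraction(var_A1: float, var_A2: float, var_D: float) -> float:
    """Dominance share of the F1 total genetic variance from the gametic
    variances and the SCA variance: var_D / (var_A1/2 + var_A2/2 + var_D)."""
    var_A = 0.5 * var_A1 + 0.5 * var_A2
    return var_D / (var_A + var_D)
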
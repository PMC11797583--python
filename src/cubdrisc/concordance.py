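"""Chance-corrected agreement between dichotomised risk scales.

When two questionnaires are dichotomised at the same cutoff (score ≥ cutoff
⇒ test-positive), their agreement beyond chance is measured with Cohen's
kappa, κ = (p_o − p_e)/(1 − p_e), where p_o is the observed agreement and
p_e the agreement expected from the marginal positivity rates.  Strength is
graded on the six Landis–Koch levels: ≤ 0.00 poor, 0.01–0.20 slight,
0.21–0.40 acceptable, 0.41–0.60 moderate, 0.61–0.80 considerable,
0.81–1.00 almost perfect.

Two standard errors are carried: the Fleiss–Cohen–Everitt large-sample SE
(reported alongside κ) and the SE under H0: κ = 0 (used for the two-sided
p-value), matching common statistical-package output.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "KappaStrength",
    "KappaResult",
    "UndefinedKappaError",
    "cohen_kappa",
    "kappa_strength",
    "concordance_sweep",
    "format_concordance_tsv",
]


class KappaStrength(str, enum.Enum):
    POOR = "poor"
    SLIGHT = "slight"
    ACCEPTABLE = "acceptable"
    MODERATE = "moderate"
    CONSIDERABLE = "considerable"
    ALMOST_PERFECT = "almost_perfect"


class UndefinedKappaError(ValueError):
    """Both raters are constant: p_e = 1 and kappa is undefined."""


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    standard_error: float
    p_value: float
    strength: KappaStrength
    p_observed: float
    p_expected: float
    n: int


def kappa_strength(kappa: float) -> KappaStrength:
    """Landis–Koch grade of a kappa value.

    Non-positive values are "poor"; positive values are banded after
    round-half-up to two decimals (the reporting precision), so any positive
    agreement below 0.005 still grades "slight" rather than "poor".
    """
    if not -1 <= kappa <= 1 + 1e-12:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa <= 0:
        return KappaStrength.POOR
    k2 = float(Decimal(repr(kappa)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    if k2 <= 0.20:
        return KappaStrength.SLIGHT
    if k2 <= 0.40:
        return KappaStrength.ACCEPTABLE
    if k2 <= 0.60:
        return KappaStrength.MODERATE
    if k2 <= 0.80:
        return KappaStrength.CONSIDERABLE
    return KappaStrength.ALMOST_PERFECT


def cohen_kappa(a: Sequence[bool], b: Sequence[bool]) -> KappaResult:
    """Cohen's kappa between two binary classifications of the same subjects.

    The reported ``standard_error`` is the Fleiss–Cohen–Everitt large-sample
    SE of κ̂; the p-value tests H0: κ = 0 with the asymptotic SE under the
    null and a two-sided normal reference.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("the two classifications must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("kappa requires at least two subjects")

    # 2x2 joint proportions: rows = rater a (F, T), cols = rater b (F, T)
    p = np.empty((2, 2))
    for i, av in enumerate((False, True)):
        for j, bv in enumerate((False, True)):
            p[i, j] = np.sum((a == av) & (b == bv)) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "both classifications are constant (chance agreement = 1); kappa is undefined"
        )
    kappa = (p_o - p_e) / (1 - p_e)

    # Fleiss-Cohen-Everitt variance of kappa-hat
    a_term = sum(
        p[i, i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(2)
    )
    b_term = (1 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    c_term = (kappa - p_e * (1 - kappa)) ** 2
    var = (a_term + b_term - c_term) / (n * (1 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))

    # SE under H0: kappa = 0, for the significance test
    var0 = (
        p_e + p_e**2 - sum(row[i] * col[i] * (row[i] + col[i]) for i in range(2))
    ) / (n * (1 - p_e) ** 2)
    se0 = math.sqrt(max(var0, 0.0))
    if se0 > 0:
        z = kappa / se0
        p_value = 2 * float(norm.sf(abs(z)))
    else:
        p_value = float("nan")

    return KappaResult(
        kappa=float(kappa),
        standard_error=se,
        p_value=p_value,
        strength=kappa_strength(float(np.clip(kappa, -1, 1))),
        p_observed=p_o,
        p_expected=p_e,
        n=n,
    )


def concordance_sweep(
    scores_by_scale: Mapping[str, Sequence[int]],
    reference: str,
    cutoffs: Sequence[int],
) -> pd.DataFrame:
    """Kappa between the reference scale and each other scale at each cutoff.

    All scales must be scored on the same participants in the same order;
    each scale is dichotomised at score ≥ cutoff before comparison.
    """
    if reference not in scores_by_scale:
        raise ValueError(f"reference scale {reference!r} is not among the scored scales")
    lengths = {k: len(np.asarray(v)) for k, v in scores_by_scale.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"scales are scored on different record counts: {lengths}")
    for c in cutoffs:
        if not 0 <= c <= 26:
            raise ValueError(f"cutoff {c} outside the attainable score range [0, 26]")

    ref_scores = np.asarray(scores_by_scale[reference])
    rows = []
    for cutoff in cutoffs:
        ref_pos = ref_scores >= cutoff
        for scale, scores in scores_by_scale.items():
            if scale == reference:
                continue
            res = cohen_kappa(ref_pos, np.asarray(scores) >= cutoff)
            rows.append(
                {
                    "cutoff": int(cutoff),
                    "scale": scale,
                    "kappa": res.kappa,
                    "standard_error": res.standard_error,
                    "p_value": res.p_value,
                    "strength": res.strength.value,
                }
            )
    return pd.DataFrame(rows)


def format_concordance_tsv(table: pd.DataFrame) -> str:
    """Concordance sweep as TSV: cutoff, scale, kappa, SE, p, strength."""
    lines = ["cutoff\tscale\tkappa\tstandard_error\tp_value\tstrength"]
    for _, r in table.iterrows():
        p = r["p_value"]
        p_str = "<0.0001" if p < 1e-4 else f"{p:.4f}"
        lines.append(
            f"{int(r['cutoff'])}\t{r['scale']}\t{r['kappa']:.3f}"
            f"\t{r['standard_error']:.3f}\t{p_str}\t{r['strength']}"
        )
    return "\n".join(lines) + "\n"
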
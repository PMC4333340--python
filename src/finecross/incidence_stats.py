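"""Incidence estimation and exact categorical tests.

Two-sided Fisher p-values use the minimum-likelihood summation rule
(summing hypergeometric probabilities of all same-margin tables no more
probable than the observed one, within relative tolerance 1e-7), the
convention of R's ``fisher.test``. Laterality bias uses the exact binomial
test against 0.5; a Fisher-style 2x2 construction against an expected
50:50 split is available behind a flag. Confidence intervals are
Clopper-Pearson at 95%.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .genome_model import ValidationError


@dataclass
class IncidenceEstimate:
    affected_count: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion

    def percent_display(self, decimals: int = 1) -> float:
        """Percentage rounded as printed (default one decimal)."""
        return round(self.percent, decimals)


def incidence(affected_count: int, n: int, confidence: float = 0.95) -> IncidenceEstimate:
    """Point estimate and exact (Clopper-Pearson) binomial CI for a proportion."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if not (0 <= affected_count <= n):
        raise ValidationError("affected_count must lie in [0, n]")
    alpha = 1.0 - confidence
    k = affected_count
    ci_low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    ci_high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return IncidenceEstimate(
        affected_count=k,
        n=n,
        proportion=k / n,
        ci_low=ci_low,
        ci_high=ci_high,
    )


@dataclass
class TwoByTwoTable:
    cells: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("positive", "negative")

    def __post_init__(self) -> None:
        flat = [c for row in self.cells for c in row]
        if any(c < 0 for c in flat):
            raise ValidationError("all cells must be non-negative")
        if sum(flat) == 0:
            raise ValidationError("at least one margin must be positive")


def fisher_exact_2x2(table: TwoByTwoTable | list | tuple) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood rule)."""
    if not isinstance(table, TwoByTwoTable):
        table = TwoByTwoTable(cells=(tuple(table[0]), tuple(table[1])))
    _, p = stats.fisher_exact(table.cells, alternative="two-sided")
    return float(p)


def side_bias_test(
    k_right: int, n_unilateral: int, method: str = "binomial"
) -> float:
    """Two-sided exact test of right-vs-left balance among unilateral cases.

    ``method='binomial'``: exact binomial test against 0.5 (bilateral cases
    must be excluded upstream). ``method='fisher'``: 2x2 Fisher comparison
    of the observed split against an expected even split of the same n.
    """
    if n_unilateral <= 0:
        raise ValidationError("n_unilateral must be positive")
    if not (0 <= k_right <= n_unilateral):
        raise ValidationError("k_right must lie in [0, n_unilateral]")
    if method == "binomial":
        return float(stats.binomtest(k_right, n_unilateral, p=0.5).pvalue)
    if method == "fisher":
        half = n_unilateral // 2
        return fisher_exact_2x2(
            [[k_right, n_unilateral - k_right], [half, n_unilateral - half]]
        )
    raise ValidationError(f"unknown method {method!r}")
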
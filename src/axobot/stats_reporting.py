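"""Population statistics: attrition tables and reconnection contingency tests.

Fisher's exact test is implemented directly from the hypergeometric
distribution using the conventional two-sided "small-p" rule: the p-value is
the sum of the probabilities of all tables (with the observed margins) whose
probability does not exceed that of the observed table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .errors import InputError

__all__ = ["ContingencyTable2x2", "ReconnectionReport", "AttritionSummary",
           "fisher_exact_2x2", "attrition_summary", "summarize_reconnection",
           "STEP_ORDER"]

# Flush reasons in pipeline order; attrition is bookkept per step of total.
STEP_ORDER = ("trap", "coarse_focus", "verify", "axotomy")
_STEP_TITLES = {
    "trap": "Step 1 (trap + locate)",
    "coarse_focus": "Step 2 (coarse focus)",
    "verify": "Step 3 (verify neuron)",
    "axotomy": "Step 4 (axotomy)",
}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows are groups, columns success/failure."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise InputError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) == 0:
            raise InputError("table total must be positive")


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Returns 1.0 by convention when any margin is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    # Tolerance guards against ties lost to floating-point rounding.
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(p, 1.0)


@dataclass
class AttritionSummary:
    """Per-step rejection bookkeeping over a processed population."""

    n_processed: int
    n_success: int
    rejections: dict[str, int]                 # per step, of total
    rejection_fractions: dict[str, float]
    remaining_pct: dict[str, float]            # cumulative, after each step
    success_pct: float
    mean_durations_s: dict[str, float] = field(default_factory=dict)
    sd_durations_s: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_success + sum(self.rejections.values()) != self.n_processed:
            raise InputError("attrition counts do not conserve the population")

    def to_text(self) -> str:
        lines = [f"processed worms: {self.n_processed}"]
        for step in STEP_ORDER:
            lines.append(
                f"  {_STEP_TITLES[step]}: rejected {self.rejections[step]}"
                f" ({100 * self.rejection_fractions[step]:.1f}% of total),"
                f" remaining {self.remaining_pct[step]:.1f}%"
            )
        lines.append(f"overall success: {self.n_success}"
                     f" ({self.success_pct:.1f}%)")
        return "\n".join(lines)


def attrition_summary(records) -> AttritionSummary:
    """Summarize a list of per-worm automation records.

    Each record needs ``outcome`` ("success"/"flushed"), ``flush_reason``
    (one of :data:`STEP_ORDER` when flushed) and optionally
    ``step_durations_s`` (mapping step -> seconds).
    """
    records = list(records)
    if not records:
        raise InputError("no records to summarize")

    def get(rec, name, default=None):
        if isinstance(rec, dict):
            return rec.get(name, default)
        return getattr(rec, name, default)

    n = len(records)
    rejections = {step: 0 for step in STEP_ORDER}
    n_success = 0
    durations: dict[str, list[float]] = {step: [] for step in STEP_ORDER}
    for rec in records:
        if get(rec, "outcome") == "success":
            n_success += 1
        else:
            reason = get(rec, "flush_reason")
            if reason not in rejections:
                raise InputError(f"unknown flush reason {reason!r}")
            rejections[reason] += 1
        for step, dt in (get(rec, "step_durations_s") or {}).items():
            durations[step].append(dt)

    fractions = {s: rejections[s] / n for s in STEP_ORDER}
    remaining = {}
    running = 1.0
    for step in STEP_ORDER:
        running -= fractions[step]
        remaining[step] = 100.0 * running
    return AttritionSummary(
        n_processed=n,
        n_success=n_success,
        rejections=rejections,
        rejection_fractions=fractions,
        remaining_pct=remaining,
        success_pct=100.0 * n_success / n,
        mean_durations_s={s: float(np.mean(v)) for s, v in durations.items() if v},
        sd_durations_s={s: float(np.std(v, ddof=1)) for s, v in durations.items()
                        if len(v) > 1},
    )


@dataclass
class ReconnectionReport:
    group_a: tuple[int, int]     # (reconnected, total)
    group_b: tuple[int, int]
    rate_a: float                # exact fraction
    rate_b: float
    rate_a_pct: int              # rounded display percent
    rate_b_pct: int
    p_value: float
    significant: bool            # at alpha = 0.05

    def to_text(self) -> str:
        verdict = "significant" if self.significant else "not significant"
        return (
            f"group A: {self.group_a[0]}/{self.group_a[1]} = {self.rate_a_pct}%\n"
            f"group B: {self.group_b[0]}/{self.group_b[1]} = {self.rate_b_pct}%\n"
            f"Fisher's exact test (two-sided): p = {self.p_value:.2f} ({verdict})"
        )


def summarize_reconnection(group_a: tuple[int, int],
                           group_b: tuple[int, int],
                           alpha: float = 0.05) -> ReconnectionReport:
    """Compare reconnection counts (successes, total) of two groups."""
    for succ, total in (group_a, group_b):
        if total <= 0:
            raise InputError("group totals must be positive")
        if not 0 <= succ <= total:
            raise InputError("successes must lie within [0, total]")
    table = ContingencyTable2x2(group_a[0], group_a[1] - group_a[0],
                                group_b[0], group_b[1] - group_b[0])
    p = fisher_exact_2x2(table)
    rate_a = group_a[0] / group_a[1]
    rate_b = group_b[0] / group_b[1]
    return ReconnectionReport(
        group_a=group_a, group_b=group_b,
        rate_a=rate_a, rate_b=rate_b,
        rate_a_pct=round(100.0 * rate_a), rate_b_pct=round(100.0 * rate_b),
        p_value=p, significant=p < alpha,
    )
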
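"""Test 2.CT: contingency-table detection of immediate trap response.

For each occasion i the test contrasts animals captured at i with
animals not captured at i but known to be alive there (captured both
before and after), asking whether the next recapture comes immediately
(at i+1) or later.  Under independence of successive captures the two
groups behave alike; trap-happiness shows up as an excess of immediate
recaptures among the captured-at-i group, trap-shyness as a deficit.

Convention adopted here (the construction is printed so it can be
audited): per-occasion 2x2 tables for i = 2..K-2, each contributing a
chi-square component (plain Pearson by default — the Yates continuity
correction is available but makes the test conservative at typical study
sizes — and Fisher's exact converted to a chi-square equivalent when any
expected cell is small); the overall statistic is the sum of informative
components on as many degrees of freedom; the directional statistic is
the normalized sum of signed square roots of the components, positive
for trap-happiness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import DataError, EncounterData


@dataclass
class ComponentResult:
    occasion: int
    table: np.ndarray          # rows: captured at i / not captured; cols: at i+1 / later
    stat: float | None         # chi-square(1) component, None if uninformative
    sign: int                  # +1 trap-happy direction, -1 trap-shy, 0 none
    p_value: float | None
    method: str                # "pearson", "fisher" or "skipped"


@dataclass
class Test2CTResult:
    components: list[ComponentResult]
    overall_chi2: float
    df: int
    p_value: float | None
    z_directional: float | None
    p_value_directional: float | None

    @property
    def tables(self) -> dict[int, np.ndarray]:
        return {c.occasion: c.table for c in self.components}

    def report(self) -> str:
        lines = ["Test 2.CT — immediate trap response",
                 f"{'occ i':>5} {'seen@i:i+1':>11} {'seen@i:later':>13} "
                 f"{'miss@i:i+1':>11} {'miss@i:later':>13} {'chi2':>8} {'sign':>5} method"]
        for c in self.components:
            t = c.table
            stat = f"{c.stat:8.3f}" if c.stat is not None else "       -"
            lines.append(f"{c.occasion:>5} {t[0,0]:>11} {t[0,1]:>13} "
                         f"{t[1,0]:>11} {t[1,1]:>13} {stat} {c.sign:>5} {c.method}")
        if self.df > 0:
            lines.append(f"overall chi2 = {self.overall_chi2:.3f} on {self.df} df, "
                         f"p = {self.p_value:.4g}")
            lines.append(f"directional z = {self.z_directional:.3f} "
                         f"(positive = trap-happy), p = {self.p_value_directional:.4g}")
        else:
            lines.append("no informative table: test undefined (df = 0)")
        return "\n".join(lines)


def _component(table: np.ndarray, *, continuity: bool,
               fisher_threshold: float) -> tuple[float | None, int, float | None, str]:
    rowsum = table.sum(axis=1)
    colsum = table.sum(axis=0)
    total = table.sum()
    if (rowsum == 0).any() or (colsum == 0).any():
        return None, 0, None, "skipped"
    # direction: do captured-at-i animals come back immediately more often?
    diff = table[0, 0] / rowsum[0] - table[1, 0] / rowsum[1]
    sign = 1 if diff > 0 else (-1 if diff < 0 else 0)
    expected = np.outer(rowsum, colsum) / total
    if (expected < fisher_threshold).any():
        _, p = stats.fisher_exact(table, alternative="two-sided")
        stat = float(stats.chi2.isf(min(max(p, 1e-300), 1.0), 1)) if p < 1.0 else 0.0
        return stat, sign, float(p), "fisher"
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(stat), sign, float(p), "pearson"


def test_2ct(
    data: EncounterData,
    *,
    continuity: bool = False,
    fisher_threshold: float = 2.0,
) -> Test2CTResult:
    """Run Test 2.CT on single-state encounter data (K >= 4).

    Counts are weighted by row multiplicities.  Each table at occasion i
    is restricted to animals re-encountered after i; its rows are
    (captured at i) vs (not captured at i but captured before i), its
    columns (next encounter at i+1) vs (next encounter after i+1).
    Tables with a null margin are skipped and do not count towards the
    degrees of freedom.
    """
    if data.max_code > 1:
        raise DataError("Test 2.CT is defined for single-state data")
    K = data.n_occasions
    if K < 4:
        raise DataError("Test 2.CT needs at least 4 occasions (no informative table)")

    h = data.histories
    counts = data.counts
    components: list[ComponentResult] = []
    for i in range(2, K - 1):  # occasions 2..K-2, 1-based
        at_i = h[:, i - 1] == 1
        before = (h[:, : i - 1] == 1).any(axis=1)
        after = (h[:, i:] == 1).any(axis=1)
        next_occ = np.argmax(h[:, i:] == 1, axis=1)  # 0 <=> next capture at i+1
        include = after & (at_i | before)
        row = np.where(at_i, 0, 1)
        col = np.where(next_occ == 0, 0, 1)
        table = np.zeros((2, 2), dtype=np.int64)
        for r in (0, 1):
            for c in (0, 1):
                sel = include & (row == r) & (col == c)
                table[r, c] = counts[sel].sum()
        stat, sign, p, method = _component(
            table, continuity=continuity, fisher_threshold=fisher_threshold
        )
        components.append(ComponentResult(i, table, stat, sign, p, method))

    informative = [c for c in components if c.stat is not None]
    df = len(informative)
    if df == 0:
        return Test2CTResult(components, 0.0, 0, None, None, None)
    overall = float(sum(c.stat for c in informative))
    p_overall = float(stats.chi2.sf(overall, df))
    z = float(sum(c.sign * np.sqrt(c.stat) for c in informative) / np.sqrt(df))
    p_dir = float(2.0 * stats.norm.sf(abs(z)))
    return Test2CTResult(components, overall, df, p_overall, z, p_dir)
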
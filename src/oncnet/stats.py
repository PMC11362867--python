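"""Bivariate association tables (Pearson chi-square).

Exposure-by-attribute contingency tables are compared with the Pearson
chi-square test for independence. Two-by-two tables use the Yates continuity
correction; larger tables do not. That asymmetry matches the convention of
the major statistical packages (e.g. R's ``chisq.test``) and is pinned by
unit tests against published table values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    continuity_corrected: bool

    def __str__(self) -> str:  # 1-dp display convention for reports
        return f"chi2_{self.df} = {self.statistic:.1f} (p = {self.p_value:.3g})"


def pearson_chi2(table: pd.DataFrame | np.ndarray) -> Chi2Result:
    """Pearson chi-square test of independence on a contingency table.

    2x2 tables are continuity-corrected (|O-E| reduced by 0.5); larger
    tables are not. A zero row or column margin is rejected with an error
    naming the degenerate level.
    """
    values = np.asarray(table, dtype=float)
    if values.ndim != 2 or min(values.shape) < 2:
        raise ValueError("table must be 2-dimensional with >=2 rows and columns")
    if (values < 0).any() or not np.isfinite(values).all():
        raise ValueError("cell counts must be finite and non-negative")
    for axis, kind in ((1, "row"), (0, "column")):
        margins = values.sum(axis=axis)
        bad = np.flatnonzero(margins == 0)
        if bad.size:
            labels = (
                (table.index if kind == "row" else table.columns)[bad].tolist()
                if isinstance(table, pd.DataFrame)
                else bad.tolist()
            )
            raise ValueError(f"zero {kind} margin for level(s) {labels}")
    corrected = values.shape == (2, 2)
    statistic, p_value, df, _ = chi2_contingency(values, correction=corrected)
    return Chi2Result(float(statistic), int(df), float(p_value), corrected)


@dataclass
class BivariateTable:
    attribute: str
    counts: pd.DataFrame  # levels x exposure groups
    chi2: Chi2Result

    def formatted(self) -> pd.DataFrame:
        """count (column %) cells, the presentation used in cohort tables."""
        pct = self.counts / self.counts.sum(axis=0) * 100.0
        return pd.DataFrame(
            {
                col: [
                    f"{int(self.counts.loc[lvl, col])} ({pct.loc[lvl, col]:.1f})"
                    for lvl in self.counts.index
                ]
                for col in self.counts.columns
            },
            index=self.counts.index,
        )


def bivariate_report(
    rows: pd.DataFrame,
    attributes: list[str],
    exposure: str,
) -> list[BivariateTable]:
    """Cross-tabulate each attribute against the exposure with a chi-square test.

    Attributes with a single observed level are skipped with a warning.
    """
    out = []
    for attr in attributes:
        counts = pd.crosstab(rows[attr], rows[exposure])
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            logger.warning("attribute %r has a single level; skipped", attr)
            continue
        out.append(BivariateTable(attr, counts, pearson_chi2(counts)))
    return out


def report_text(tables: list[BivariateTable]) -> str:
    """Human-readable bivariate report mirroring a cohort-characteristics table."""
    blocks = []
    for t in tables:
        blocks.append(f"## {t.attribute}\n{t.formatted().to_string()}\n{t.chi2}")
    return "\n\n".join(blocks) + "\n"
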
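"""Small-sample assay statistics: ChIP-qPCR percent input, paired t-tests
(raw and on log2 ratios), and the differential-expression threshold filter.

Percent input expresses a ChIP qPCR signal relative to input chromatin,
correcting the input Ct for the fraction of chromatin assayed:

    percent_input = 100 * 2^(adjusted_input_ct - ct_ip)
    adjusted_input_ct = ct_input - log2(1 / input_fraction)

One qPCR cycle is a twofold difference, so percent input halves per added
IP cycle. The "ratio paired t-test" is the classic paired t-test applied to
log2 of within-pair ratios (base 2 matches the cycle arithmetic); pairs
with zero log-ratio variance are flagged indeterminate rather than given a
degenerate p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ASSAY_ALPHA = 0.05


@dataclass(frozen=True)
class QpcrMeasurement:
    region_id: str
    replicate_id: str
    ct_ip: float
    ct_input: float
    input_fraction: float  # fraction of chromatin used as input, in (0, 1]

    def __post_init__(self) -> None:
        for label, v in (("ct_ip", self.ct_ip), ("ct_input", self.ct_input)):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{label} must be finite and positive, got {v}")
        if not (0 < self.input_fraction <= 1):
            raise ValueError(
                f"input_fraction must be in (0, 1], got {self.input_fraction}"
            )


@dataclass(frozen=True)
class PairedTestResult:
    t: float | None
    df: int
    p_value: float | None
    tail: str  # "one" or "two"
    log_scale: bool
    indeterminate: bool = False


def percent_input(m: QpcrMeasurement) -> float:
    """ChIP signal as percent of (dilution-adjusted) input chromatin."""
    adjusted_input_ct = m.ct_input - math.log2(1.0 / m.input_fraction)
    return 100.0 * 2.0 ** (adjusted_input_ct - m.ct_ip)


def _paired_t(diffs: np.ndarray, tail: str, log_scale: bool) -> PairedTestResult:
    if tail not in ("one", "two"):
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    n = len(diffs)
    if n < 2:
        raise ValueError("paired test requires n >= 2")
    df = n - 1
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        return PairedTestResult(None, df, None, tail, log_scale, indeterminate=True)
    t = float(np.mean(diffs)) / (sd / math.sqrt(n))
    if tail == "one":
        p = float(stats.t.sf(t, df))  # upper tail: first sample greater
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedTestResult(t, df, min(p, 1.0), tail, log_scale)


def ratio_paired_ttest(
    x: Sequence[float], y: Sequence[float], tail: str = "one"
) -> PairedTestResult:
    """Paired t-test on log2(x_i / y_i); one-tailed tests x > y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("ratio paired t-test requires strictly positive values")
    return _paired_t(np.log2(x / y), tail, log_scale=True)


def paired_ttest(
    x: Sequence[float], y: Sequence[float], tail: str = "two"
) -> PairedTestResult:
    """Classic paired t-test on raw differences x_i - y_i."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return _paired_t(x - y, tail, log_scale=False)


def de_filter(
    table: pd.DataFrame,
    lfc_min: float = 1.5,
    padj_max: float = 0.1,
    absolute: bool = False,
) -> set[str]:
    """Differential-expression threshold filter over a results table.

    Keeps genes with log2fc > lfc_min (or |log2fc| > lfc_min when
    ``absolute``) and padj < padj_max, both strict. Rows with missing padj
    are skipped with a warning. Columns: gene_id, log2fc, padj.
    """
    for col in ("gene_id", "log2fc", "padj"):
        if col not in table.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    missing = table["padj"].isna()
    if missing.any():
        logger.warning(
            "de_filter: skipping %d rows with missing padj", int(missing.sum())
        )
    tab = table.loc[~missing]
    lfc = tab["log2fc"].abs() if absolute else tab["log2fc"]
    mask = (lfc > lfc_min) & (tab["padj"] < padj_max)
    return set(tab.loc[mask, "gene_id"])


def de_filter_union(
    tables: Sequence[pd.DataFrame],
    lfc_min: float = 1.5,
    padj_max: float = 0.1,
    absolute: bool = False,
) -> set[str]:
    """Genes passing the DE filter in at least one contrast (e.g. enriched
    at either of two developmental stages)."""
    out: set[str] = set()
    for tab in tables:
        out |= de_filter(tab, lfc_min, padj_max, absolute)
    return out


def chip_qpcr_enrichment(
    measurements: pd.DataFrame,
    treatment: str = "Six1",
    control: str = "IgG",
    tail: str = "one",
    alpha: float = DEFAULT_ASSAY_ALPHA,
) -> pd.DataFrame:
    """Per-region ChIP enrichment over a control antibody.

    ``measurements`` columns: region_id, replicate_id, antibody, ct_ip,
    ct_input, input_fraction. For each region the percent-input values of
    the treatment antibody are compared to the control across paired
    replicates with a ratio paired t-test. Returns a table with columns
    (comparison, n, t, df, tail, p, significant_at_alpha).
    """
    required = {
        "region_id",
        "replicate_id",
        "antibody",
        "ct_ip",
        "ct_input",
        "input_fraction",
    }
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns {sorted(missing)}")
    pi = measurements.assign(
        percent_input=[
            percent_input(
                QpcrMeasurement(
                    str(r.region_id),
                    str(r.replicate_id),
                    float(r.ct_ip),
                    float(r.ct_input),
                    float(r.input_fraction),
                )
            )
            for r in measurements.itertuples(index=False)
        ]
    )
    rows = []
    for region, grp in pi.groupby("region_id", sort=True):
        wide = grp.pivot(
            index="replicate_id", columns="antibody", values="percent_input"
        )
        if treatment not in wide.columns or control not in wide.columns:
            raise ValueError(
                f"region {region!r}: need both {treatment!r} and {control!r} "
                "measurements"
            )
        paired = wide[[treatment, control]].dropna()
        res = ratio_paired_ttest(paired[treatment], paired[control], tail)
        rows.append(
            {
                "comparison": f"{region}:{treatment}_vs_{control}",
                "n": len(paired),
                "t": res.t,
                "df": res.df,
                "tail": res.tail,
                "p": res.p_value,
                "significant_at_alpha": (
                    bool(res.p_value <= alpha) if res.p_value is not None else False
                ),
            }
        )
    return pd.DataFrame(rows)
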
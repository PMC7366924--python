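"""Interspecific-hybrid screening from dual-reference read assignment.

Reads from each individual are competitively mapped (upstream of this
package) against two reference genomes — the species of interest
(dromedary) and a close congener (Bactrian camel) — keeping only reads
that map unambiguously to one of the two.  Recent hybrids carry an
elevated share of reads assigned to the alternate reference.  The screen
computes each individual's percent-alternate statistic and flags "far out"
values under Tukey's rule: anything strictly greater than
``Q3 + 3 * (Q3 - Q1)``.

Quartiles use linear interpolation on order statistics (the default of
the major scientific stacks); the quartiles and threshold are included in
the report so alternative conventions can be audited against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HybridScreenReport:
    """Outcome of the far-out screen over one cohort."""

    table: pd.DataFrame  # sample, reads_primary, reads_alt, percent_alt, flagged
    q1: float
    q3: float
    threshold: float

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "sample"])


def percent_alt_reference(table: pd.DataFrame) -> pd.Series:
    """Percent of unambiguously mapped reads assigned to the alternate
    reference: ``100 * alt / (primary + alt)`` per sample.

    Raises for any sample whose total unambiguous count is zero.
    """
    primary = table["reads_primary"].to_numpy(dtype=float)
    alt = table["reads_alt"].to_numpy(dtype=float)
    if (primary < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    total = primary + alt
    zero = total == 0
    if zero.any():
        bad = table.loc[zero, "sample"].tolist()
        raise ValueError(f"samples with zero unambiguously mapped reads: {bad}")
    return pd.Series(100.0 * alt / total, index=table.index, name="percent_alt")


def far_out_threshold(values) -> tuple[float, float, float]:
    """Tukey far-out threshold ``Q3 + 3*IQR``.

    Returns ``(q1, q3, threshold)``.  Requires at least 4 values so the
    quartiles are not degenerate summaries of the whole sample.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("far-out rule needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q1), float(q3), float(q3 + 3.0 * (q3 - q1))


def flag_hybrids(table: pd.DataFrame) -> HybridScreenReport:
    """Run the full screen: percent statistic, far-out threshold, flags.

    Samples with percent strictly greater than the threshold are flagged.
    """
    pct = percent_alt_reference(table)
    q1, q3, thr = far_out_threshold(pct.to_numpy())
    out = table.copy()
    out["percent_alt"] = pct
    out["flagged"] = pct > thr
    return HybridScreenReport(table=out, q1=q1, q3=q3, threshold=thr)


def read_counts_table(path) -> pd.DataFrame:
    """Read a TSV with columns sample, reads_primary, reads_alt."""
    table = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "reads_primary", "reads_alt"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return table


def write_report(report: HybridScreenReport, path) -> None:
    out = report.table.copy()
    out["q1"] = report.q1
    out["q3"] = report.q3
    out["threshold"] = report.threshold
    out.to_csv(path, sep="\t", index=False)
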
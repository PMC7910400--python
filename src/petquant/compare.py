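"""Cross-scanner comparison of regional quantification parameters.

Two scanners measuring the same subject should return the same regional
BP_ND or uptake ratio; the comparison report is the element-wise ratio
of scanner A to scanner B per region, the percent deviation
``|ratio - 1| * 100``, and, across subjects, the arithmetic mean of the
per-subject ratios per tracer and region (mean of ratios, not ratio of
means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import InvalidSpecError

__all__ = ["ScannerRecord", "ComparisonReport", "scanner_ratio", "mean_ratios"]


@dataclass(frozen=True)
class ScannerRecord:
    """Regional parameter values (BP_ND or ratio) from one scan."""

    scanner: str
    subject: str
    tracer: str
    values: Mapping[str, float]


@dataclass(frozen=True)
class ComparisonReport:
    """Per-region scanner-A/scanner-B ratios for one subject.

    ``deviations`` are ``|ratio - 1| * 100`` in percent.
    """

    scanner_a: str
    scanner_b: str
    subject: str
    tracer: str
    ratios: dict[str, float]
    deviations: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scanner_a": self.scanner_a,
                "scanner_b": self.scanner_b,
                "subject": self.subject,
                "tracer": self.tracer,
                "region": list(self.ratios),
                "ratio": list(self.ratios.values()),
                "deviation_pct": [self.deviations[r] for r in self.ratios],
            }
        )


def scanner_ratio(a: ScannerRecord, b: ScannerRecord) -> ComparisonReport:
    """Element-wise ratio a/b over matched regions.

    Raises naming the offending region if the region sets differ.
    """
    missing_in_b = sorted(set(a.values) - set(b.values))
    missing_in_a = sorted(set(b.values) - set(a.values))
    if missing_in_b or missing_in_a:
        parts = []
        if missing_in_b:
            parts.append(f"missing in {b.scanner}: {missing_in_b}")
        if missing_in_a:
            parts.append(f"missing in {a.scanner}: {missing_in_a}")
        raise InvalidSpecError("region mismatch between records; " + "; ".join(parts))
    ratios = {r: a.values[r] / b.values[r] for r in a.values}
    deviations = {r: abs(v - 1.0) * 100.0 for r, v in ratios.items()}
    return ComparisonReport(
        scanner_a=a.scanner,
        scanner_b=b.scanner,
        subject=a.subject,
        tracer=a.tracer,
        ratios=ratios,
        deviations=deviations,
    )


def mean_ratios(reports: Sequence[ComparisonReport]) -> pd.DataFrame:
    """Arithmetic mean of per-subject ratios, per tracer and region."""
    if not reports:
        raise InvalidSpecError("no comparison reports supplied")
    df = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    out = (
        df.groupby(["tracer", "region"], sort=True)
        .agg(
            mean_ratio=("ratio", "mean"),
            mean_deviation_pct=("deviation_pct", "mean"),
            n_subjects=("subject", "nunique"),
        )
        .reset_index()
    )
    return out
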
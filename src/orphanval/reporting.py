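"""Run manifests and table/CSV/JSON writers.

Every command embeds a :class:`RunManifest` in its outputs so that a run can
be reproduced bit-for-bit: scenario file and content hash, seed, path count,
engine version, and the cash-flow convention flags actually used. Monetary
tables are rendered in $M at two decimals; internal arithmetic is never
rounded.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .engine import Conventions, ValuationResult
from .montecarlo import RiskSummary, SimPaths


@dataclass
class RunManifest:
    scenario_path: Optional[str]
    scenario_sha256: Optional[str]
    seed: Optional[int]
    n_paths: Optional[int]
    conventions: dict
    engine_version: str = __version__
    cross_drug_rho: Optional[float] = None
    extra: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @classmethod
    def for_run(
        cls,
        scenario_path: Optional[str | Path],
        conventions: Conventions,
        *,
        seed: Optional[int] = None,
        n_paths: Optional[int] = None,
        cross_drug_rho: Optional[float] = None,
        **extra,
    ) -> "RunManifest":
        sha = None
        if scenario_path is not None:
            sha = hashlib.sha256(Path(scenario_path).read_bytes()).hexdigest()
        return cls(
            scenario_path=str(scenario_path) if scenario_path else None,
            scenario_sha256=sha,
            seed=seed,
            n_paths=n_paths,
            conventions=conventions.as_dict(),
            cross_drug_rho=cross_drug_rho,
            extra=dict(extra),
        )

    def to_dict(self) -> dict:
        return {
            "scenario_path": self.scenario_path,
            "scenario_sha256": self.scenario_sha256,
            "seed": self.seed,
            "n_paths": self.n_paths,
            "engine_version": self.engine_version,
            "conventions": self.conventions,
            "cross_drug_rho": self.cross_drug_rho,
            "extra": self.extra,
            "timestamp": self.timestamp,
        }

    def header_lines(self) -> list[str]:
        d = self.to_dict()
        d.pop("timestamp")  # keep rendered tables byte-stable across reruns
        return [f"# {k}: {v}" for k, v in d.items() if v is not None]


def write_valuation_json(
    result: ValuationResult, manifest: RunManifest, path: str | Path
) -> None:
    payload = {"manifest": manifest.to_dict(), "valuation": result.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_summary_json(
    summary: RiskSummary, manifest: RunManifest, path: str | Path
) -> None:
    payload = {"manifest": manifest.to_dict(), "summary": summary.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def render_table(
    summary: RiskSummary,
    layout: str = "table-4",
    *,
    expected: Optional[np.ndarray] = None,
    overall_expected: Optional[float] = None,
    manifest: Optional[RunManifest] = None,
) -> str:
    """Render a risk summary as CSV text in one of the report layouts.

    ``table-4`` / ``table-5``: one row per phase plus an Overall row, with
    the deterministic expected value (if supplied), the Monte Carlo mean and
    sd of the conditional value distribution, and the upper-bound
    percentile. ``portfolio``: the same rows for aggregate values, with the
    cross-drug correlation recorded in the header. Cells are $M at two
    decimals; empty conditional sets render "NA".
    """
    if layout not in ("table-4", "table-5", "portfolio"):
        raise ValueError(f"unknown layout {layout!r}")
    if layout == "portfolio" and summary.cross_drug_rho is None:
        raise ValueError("portfolio layout requires a portfolio summary")
    k = len(summary.phase_names)
    exp = (
        [np.nan] * k
        if expected is None
        else list(np.asarray(expected, dtype=float))
    )
    rows = []
    for j, name in enumerate(summary.phase_names):
        rows.append(
            {
                "phase": name,
                "expected_value": exp[j],
                "mc_mean": summary.value_mean[j],
                "mc_sd": summary.value_sd[j],
                "upper_bound": summary.value_upper[j],
            }
        )
    rows.append(
        {
            "phase": "Overall",
            "expected_value": (
                np.nan if overall_expected is None else overall_expected
            ),
            "mc_mean": summary.overall_rnpv_mean,
            "mc_sd": summary.overall_rnpv_sd,
            "upper_bound": summary.overall_rnpv_upper,
        }
    )
    df = pd.DataFrame(rows)
    for c in df.columns[1:]:
        df[c] = df[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.2f}")
    buf = io.StringIO()
    header = manifest.header_lines() if manifest is not None else []
    if layout == "portfolio":
        header.append(
            f"# assumption cross_drug_rho: {summary.cross_drug_rho}"
            f" (n_drugs={summary.n_drugs})"
        )
    for line in header:
        buf.write(line + "\n")
    df.to_csv(buf, index=False)
    return buf.getvalue()


def histogram_csv(
    values: np.ndarray, path: str | Path, *, bins: int = 60
) -> pd.DataFrame:
    """Bin values for a histogram and write (bin_left, bin_right, count)."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
    df = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    df.to_csv(path, index=False)
    return df


def write_paths_csv(paths: SimPaths, path: str | Path) -> None:
    paths.to_dataframe().to_csv(path, index=False)
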
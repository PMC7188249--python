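"""Table-style reporting of solutions.

One row per intervention with the ICER at the funded coverage level, the
coverage itself, DALYs averted and equity-weighted DALYs averted, plus a
totals row - the standard layout of a benefit-package league-table report.
Coverage is formatted as percent only here; everything upstream is
fractional.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .data_model import AnalysisConfig, fixture_bytes
from .optimizer import Solution

__all__ = ["ReportBundle", "solution_frame", "comparison_frame"]


def solution_frame(solution: Solution) -> pd.DataFrame:
    """Per-intervention report table for one scenario."""
    rows = []
    for o in solution.outcomes:
        rows.append(
            {
                "intervention": o.name,
                "icer_at_coverage": round(o.last_icer) if o.last_icer is not None else None,
                "coverage_pct": round(o.coverage * 100.0, 2),
                "dalys_averted": o.dalys,
                "equity_weighted_dalys_averted": o.weighted_dalys,
                "spend_usd": o.spend,
            }
        )
    rows.append(
        {
            "intervention": "Total",
            "icer_at_coverage": None,
            "coverage_pct": None,
            "dalys_averted": solution.total_dalys,
            "equity_weighted_dalys_averted": solution.total_weighted_dalys,
            "spend_usd": solution.total_spend,
        }
    )
    return pd.DataFrame(rows)


def comparison_frame(solutions: Mapping[str, Solution]) -> pd.DataFrame:
    """Scenario-comparison summary (totals, marginal ICERs, underspend)."""
    rows = []
    for name, sol in solutions.items():
        rows.append(
            {
                "scenario": name,
                "total_spend_usd": sol.total_spend,
                "total_dalys": sol.total_dalys,
                "total_weighted_dalys": sol.total_weighted_dalys,
                "marginal_icer": sol.marginal_icer,
                "pre_fractional_underspend_usd": sol.pre_fractional_underspend,
                "n_covered": sol.n_covered,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """Per-scenario tables plus a provenance block.

    Every number in the bundle is read straight from a ``Solution``;
    regenerating the bundle from the same solutions is byte-identical.
    """

    solutions: dict[str, Solution]
    config: AnalysisConfig
    data_source: str = "builtin"
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            digest = (
                hashlib.sha256(fixture_bytes()).hexdigest()
                if self.data_source == "builtin"
                else None
            )
            self.provenance = {
                "version": __version__,
                "data_source": self.data_source,
                "fixture_sha256": digest,
                "conversion_factor": self.config.conversion_factor,
                "seed": self.seed,
                "config": self.config.to_json_obj(),
            }

    def to_json_obj(self) -> dict:
        return {
            "provenance": self.provenance,
            "solutions": {k: s.to_json_obj() for k, s in self.solutions.items()},
        }

    def write(self, out_dir: str | Path) -> list[Path]:
        """Write CSV + JSON + plain-text tables; returns the files written."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, sol in self.solutions.items():
            frame = solution_frame(sol)
            csv_path = out / f"solution_{name}.csv"
            frame.to_csv(csv_path, index=False)
            written.append(csv_path)
        summary_path = out / "summary.json"
        summary_path.write_text(
            json.dumps(self.to_json_obj(), indent=2, sort_keys=True, default=float)
        )
        written.append(summary_path)
        text_path = out / "summary.txt"
        text_path.write_text(self.render_text())
        written.append(text_path)
        return written

    def render_text(self) -> str:
        parts = [
            "uhcpack benefit-package optimization",
            f"conversion factor (2000 Int$ -> 2015 US$): "
            f"{self.config.conversion_factor:.6g}",
            f"budget (2015 US$): {self.config.budget:,.0f}",
            "",
        ]
        for name, sol in self.solutions.items():
            parts.append(f"=== scenario: {name} ===")
            frame = solution_frame(sol)
            parts.append(
                frame.to_string(
                    index=False,
                    float_format=lambda v: f"{v:,.2f}",
                    na_rep="-",
                )
            )
            if sol.marginal_icer is not None:
                parts.append(
                    f"marginal ICER (last funded increment): "
                    f"{sol.marginal_icer:,.0f} US$/DALY"
                    + (
                        f" ({sol.marginal_intervention_id})"
                        if sol.marginal_intervention_id
                        else ""
                    )
                )
            parts.append("")
        parts.append("--- scenario comparison ---")
        parts.append(
            comparison_frame(self.solutions).to_string(
                index=False, float_format=lambda v: f"{v:,.2f}", na_rep="-"
            )
        )
        parts.append("")
        return "\n".join(parts)

    def plot_coverage(self, path: str | Path) -> Path:
        """Grouped bar chart of funded coverage per intervention/scenario."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = [o.name for o in next(iter(self.solutions.values())).outcomes]
        x = range(len(names))
        width = 0.8 / max(len(self.solutions), 1)
        fig, ax = plt.subplots(figsize=(11, 5))
        for j, (scen, sol) in enumerate(self.solutions.items()):
            cov = [o.coverage * 100.0 for o in sol.outcomes]
            ax.bar([i + j * width for i in x], cov, width=width, label=scen)
        ax.set_xticks([i + 0.4 for i in x])
        ax.set_xticklabels(names, rotation=60, ha="right", fontsize=7)
        ax.set_ylabel("coverage (%)")
        ax.legend()
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
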
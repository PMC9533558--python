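"""Plain-text rendering of g-formula results tables.

The renderer formats values straight from the results table (risks and risk
differences in percent with two decimals, risk ratios with two decimals);
it never recomputes anything, so every rendered cell equals the
corresponding CSV value. Reference scenarios contrasted with themselves
render as RR "1", RD "0".
"""

from __future__ import annotations

import pandas as pd

__all__ = ["render_results"]


def _fmt_rr(row) -> str:
    if row["scenario"] == row["reference"]:
        return "1"
    return f"{row['rr']:.2f} ({row['rr_lo']:.2f} to {row['rr_hi']:.2f})"


def _fmt_rd(row) -> str:
    if row["scenario"] == row["reference"]:
        return "0"
    return f"{row['rd_pts']:+.2f}% ({row['rd_lo']:+.2f} to {row['rd_hi']:+.2f})"


def render_results(results: pd.DataFrame) -> str:
    """Markdown table of risks and contrasts, grouped by cause and reference."""
    lines = []
    for (cause, ref), grp in results.groupby(["cause", "reference"], sort=False):
        lines.append(f"## {cause} mortality — reference: {ref}")
        lines.append("")
        lines.append("| Intervention | Risk (%) | Risk ratio (95% CI) | Risk difference (95% CI) |")
        lines.append("|---|---|---|---|")
        for _, row in grp.iterrows():
            lines.append(
                f"| {row['scenario']} | {row['risk'] * 100:.2f} | {_fmt_rr(row)} | {_fmt_rd(row)} |"
            )
        lines.append("")
    return "\n".join(lines)
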
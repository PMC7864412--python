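"""Static rendering of the excess-mortality figure.

Draws the target-year weekly curve against its reference level, shades
excess polygons above the reference and deficit polygons below it, and
optionally overlays every other available year in light gray underneath.
Output is PNG or SVG by file extension; SVG output is byte-deterministic
for fixed inputs, so figures are reproducible artifacts.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .excess import ExcessResult
from .io import WeeklySeries, MEASURES

#: palette name -> role colors; palettes change colors only, never geometry
PALETTES = {
    "default": {
        "target": "#1f4e79", "reference": "#444444",
        "excess": "#d62728", "deficit": "#1f77b4",
        "other_years": "#cccccc",
    },
    "viridis": {
        "target": "#440154", "reference": "#35b779",
        "excess": "#fde725", "deficit": "#31688e",
        "other_years": "#d9d9d9",
    },
}


def render_excess_figure(
    result: ExcessResult,
    series: WeeklySeries,
    out_path: str | Path,
    show_other_years: bool = False,
    palette: str = "default",
    figsize: tuple[float, float] = (9.0, 5.0),
    dpi: int = 150,
) -> Path:
    """Render *result* to *out_path* (``.png`` or ``.svg``).

    The legend identifies the target year, the reference method and the
    reference period, so the image is self-describing.  Each shaded
    polygon is tagged with an SVG group id ``stmfx-polygon-<k>``.
    """
    if not result.per_week:
        raise ValueError("cannot render an empty excess result")
    pal = PALETTES.get(palette)
    if pal is None:
        raise ValueError(f"unknown palette {palette!r}; available: {sorted(PALETTES)}")
    out_path = Path(out_path)

    # svg.fonttype "none" keeps labels as text elements (searchable, smaller);
    # the fixed hashsalt makes SVG ids, and hence whole files, reproducible
    with plt.rc_context({"svg.hashsalt": "stmfx", "svg.fonttype": "none"}):
        fig, ax = plt.subplots(figsize=figsize, dpi=dpi)

        if show_other_years:
            for year in series.years:
                if year == result.target_year:
                    continue
                weeks = series.weeks_in_year(year)
                vals = [series.values[(year, w)] for w in weeks]
                ax.plot(weeks, vals, color=pal["other_years"], linewidth=0.9,
                        zorder=1)

        weeks = list(result.weeks)
        observed = [result.per_week[w].observed for w in weeks]
        reference = [result.per_week[w].reference for w in weeks]

        for k, poly in enumerate(result.polygons, start=1):
            pw = [w for w in weeks if poly.start_week <= w <= poly.end_week]
            coll = ax.fill_between(
                pw,
                [result.per_week[w].reference for w in pw],
                [result.per_week[w].observed for w in pw],
                color=pal[poly.sign], alpha=0.45, linewidth=0, zorder=2,
            )
            coll.set_gid(f"stmfx-polygon-{k}")

        if result.period_years:
            span = f"{result.period_years[0]}–{result.period_years[-1]}"
            ref_label = f"reference: {result.method} ({span})"
        else:
            ref_label = f"reference: {result.method}"
        ax.plot(weeks, reference, color=pal["reference"], linestyle="--",
                linewidth=1.4, zorder=3, label=ref_label)
        ax.plot(weeks, observed, color=pal["target"], linewidth=1.8, zorder=4,
                label=f"observed {result.target_year}")

        unit = "deaths" if result.measure_kind == "count" else "deaths per person-week"
        ax.set_xlabel("ISO week")
        ax.set_ylabel(f"{series.measure} ({unit})")
        ax.set_title(
            f"{series.country_code}, sex={series.sex}: {result.target_year} "
            f"vs {result.method}"
        )
        ax.legend(loc="upper right", frameon=False, fontsize=9)
        fig.tight_layout()

        if out_path.suffix.lower() == ".svg":
            fig.savefig(out_path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(out_path)
        plt.close(fig)
    return out_path
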
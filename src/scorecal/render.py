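"""Chart rendering: long-format CSV, plain-text matrices and PNG heatmaps.

The CSV preserves raw risks alongside the rounded display values; the
text and PNG layouts mirror the conventional chart arrangement — one
SBP x cholesterol matrix per (sex, smoking status, age) panel.
"""

from __future__ import annotations

import io

import pandas as pd

from .chart import ChartGrid, category, display_value
from .domain import SEXES
from .errors import ValidationError

FORMATS = ("csv", "text", "png")


def grid_to_frame(grid: ChartGrid) -> pd.DataFrame:
    """One row per cell: identifiers, raw risk, display value, category."""
    rows = []
    for (sex, smoker, age, sbp, chol), risk in sorted(grid.cells.items()):
        rows.append(
            {
                "chol_measure": grid.chol_measure.value,
                "sex": sex,
                "smoker": int(smoker),
                "age": age,
                "sbp": sbp,
                "chol": chol,
                "risk_raw": risk,
                "risk_display": display_value(risk),
                "category": category(risk),
            }
        )
    return pd.DataFrame(rows)


def render_text(grid: ChartGrid) -> str:
    """Plain-text matrix layout, one panel per sex/smoking/age."""
    out = io.StringIO()
    sbps = sorted(grid.axes.sbp_levels, reverse=True)
    chols = list(grid.axes.chol_levels)
    for sex in SEXES:
        for smoker in (False, True):
            for age in grid.axes.ages:
                label = f"{sex}, {'smoker' if smoker else 'non-smoker'}, age {age}"
                out.write(f"{label}\n")
                head = "SBP\\chol " + " ".join(f"{c:>5g}" for c in chols)
                out.write(head + "\n")
                for sbp in sbps:
                    vals = [display_value(grid.cells[(sex, smoker, age, sbp, c)]) for c in chols]
                    out.write(f"{sbp:>8g} " + " ".join(f"{v:>5}" for v in vals) + "\n")
                out.write("\n")
    return out.getvalue()


def render_png(grid: ChartGrid, path: str) -> None:
    """Heatmap panels of display percentages, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from .chart import display_number

    ages = list(grid.axes.ages)
    sbps = sorted(grid.axes.sbp_levels, reverse=True)
    chols = list(grid.axes.chol_levels)
    panels = [(sex, smoker) for sex in SEXES for smoker in (False, True)]
    fig, axmat = plt.subplots(
        len(panels), len(ages),
        figsize=(2.1 * len(ages), 1.9 * len(panels)),
        squeeze=False,
    )
    vmax = max(display_number(v) for v in grid.cells.values()) or 1
    for i, (sex, smoker) in enumerate(panels):
        for j, age in enumerate(ages):
            m = np.array(
                [[display_number(grid.cells[(sex, smoker, age, s, c)]) for c in chols]
                 for s in sbps]
            )
            ax = axmat[i][j]
            ax.imshow(m, cmap="YlOrRd", vmin=0, vmax=vmax, aspect="auto")
            for r in range(len(sbps)):
                for c in range(len(chols)):
                    ax.text(c, r, display_value(grid.cells[(sex, smoker, age, sbps[r], chols[c])]),
                            ha="center", va="center", fontsize=7)
            ax.set_xticks(range(len(chols)), [f"{c:g}" for c in chols], fontsize=6)
            ax.set_yticks(range(len(sbps)), [f"{s:g}" for s in sbps], fontsize=6)
            if i == 0:
                ax.set_title(f"age {age}", fontsize=8)
            if j == 0:
                ax.set_ylabel(f"{sex}\n{'smoker' if smoker else 'non-smoker'}", fontsize=7)
    fig.suptitle(f"10-year fatal-CVD risk (%), {grid.chol_measure.value} chart", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_chart(grid: ChartGrid, fmt: str, path: str | None = None) -> str | None:
    """Render a grid. ``csv`` and ``text`` return the document (and write
    it when ``path`` is given); ``png`` requires ``path``."""
    if fmt not in FORMATS:
        raise ValidationError(f"unknown chart format {fmt!r}; choose from {FORMATS}")
    if fmt == "csv":
        doc = grid_to_frame(grid).to_csv(index=False, float_format="%.17g")
    elif fmt == "text":
        doc = render_text(grid)
    else:
        if path is None:
            raise ValidationError("png rendering requires an output path")
        render_png(grid, path)
        return None
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(doc)
    return doc
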
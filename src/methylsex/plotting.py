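"""Diagnostic plots: the PC1 scatter and the distribution line chart.

``plot_sex_estimation`` scatters each sample's chrX first principal component
(X.PC1) against its chrY one (Y.PC1); F/M calls form two well-separated
clouds and N-samples sit in the off-diagonal quadrants.  The reference panel
can be underlaid for context.

``plot_sex_distribution`` draws, for one or more query samples, line charts of
the chrX beta, chrY beta and chrY detection-p proportion profiles on top of
the reference panel's per-sex envelopes (per-bin median with an interquartile
band) — the visual check for Klinefelter/Turner-like signatures.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .profiles import ProfileTable
from .reference import ReferencePanel

CALL_STYLE = {
    "F": {"color": "tab:red", "marker": "o"},
    "M": {"color": "tab:green", "marker": "o"},
    "N": {"color": "tab:purple", "marker": "^"},
}
SEX_COLOR = {"f": "tab:red", "m": "tab:green"}

_PANELS = (
    ("chrX", "beta", "chrX beta-values"),
    ("chrY", "beta", "chrY beta-values"),
    ("chrY", "detp", "chrY detection p-values"),
)


def plot_sex_estimation(
    calls: pd.DataFrame,
    ref_coords: pd.DataFrame | None = None,
    include_reference: bool = True,
    out_path=None,
):
    """Scatter X.PC1 against Y.PC1, coloured by predicted sex.

    ``calls`` needs columns ``pc1_x``, ``pc1_y`` and ``predicted``; when
    ``include_reference`` is set and ``ref_coords`` is given, the panel
    samples are drawn underneath in faint colours.  Returns the figure.
    """
    if calls is None or len(calls) == 0:
        raise ValidationError("no calls to plot")
    fig, ax = plt.subplots(figsize=(6, 6))
    if include_reference and ref_coords is not None and len(ref_coords):
        for sex in ("f", "m"):
            sub = ref_coords[ref_coords["sex"] == sex]
            ax.scatter(
                sub["pc1_x"],
                sub["pc1_y"],
                s=14,
                c=SEX_COLOR[sex],
                alpha=0.25,
                marker="s",
                label=f"reference {sex}",
            )
    for call, style in CALL_STYLE.items():
        sub = calls[calls["predicted"] == call]
        if len(sub) == 0:
            continue
        ax.scatter(sub["pc1_x"], sub["pc1_y"], s=26, label=call, **style)
    ax.set_xlabel("X.PC1")
    ax.set_ylabel("Y.PC1")
    ax.legend(loc="best", fontsize=8)
    ax.set_title("Sex estimation (first principal components)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path)
    return fig


def _envelope(ax, table: pd.DataFrame, x: np.ndarray, color: str, label: str) -> None:
    q1 = table.quantile(0.25, axis=0).to_numpy()
    med = table.quantile(0.50, axis=0).to_numpy()
    q3 = table.quantile(0.75, axis=0).to_numpy()
    ax.fill_between(x, q1, q3, color=color, alpha=0.2, linewidth=0)
    ax.plot(x, med, color=color, linestyle="--", linewidth=1.2, label=label)


def plot_sex_distribution(
    profiles: ProfileTable,
    panel: ReferencePanel,
    sample_ids: Sequence[str] | None = None,
    out_path=None,
):
    """Three-panel line chart of a query's profiles over reference envelopes.

    Panels: chrX beta, chrY beta, chrY detection p.  The panel is re-binned
    to the query's scheme (misaligned schemes raise).  Returns the figure.
    """
    ids = pd.Index(sample_ids) if sample_ids is not None else profiles.sample_ids
    if len(ids) == 0:
        raise ValidationError("no samples to plot")
    missing = ids.difference(profiles.sample_ids)
    if len(missing):
        raise ValidationError(f"unknown sample IDs: {list(missing)[:5]}")
    ref = panel.rebin(profiles.scheme)

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    query_colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for ax, (chrom, metric, title) in zip(axes, _PANELS):
        table = profiles.tables[(chrom, metric)]
        x = np.arange(table.shape[1])
        for sex in ("f", "m"):
            sub = ref.tables[(chrom, metric)].loc[panel.labels == sex]
            _envelope(ax, sub, x, SEX_COLOR[sex], f"reference {sex}")
        for i, sid in enumerate(ids):
            ax.plot(
                x,
                table.loc[sid].to_numpy(),
                color=query_colors[i % len(query_colors)],
                linewidth=1.6,
                label=str(sid),
            )
        edges = profiles.scheme.edges(metric)
        ax.set_xticks(x)
        ax.set_xticklabels([f"{e:g}" for e in edges[1:]], rotation=90, fontsize=6)
        ax.set_title(title)
        ax.set_xlabel("bin upper edge")
        ax.set_ylabel("proportion of probes")
    axes[-1].legend(fontsize=7, loc="best")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path)
    return fig
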
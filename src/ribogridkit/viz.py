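"""Static publication-style plots and the per-sample HTML report.

Plots never compute statistics: every figure is drawn from an
already-computed summary table, and each image gets a sibling TSV export of
exactly the data drawn, so results remain checkable without touching
pixels.  The per-sample HTML report embeds the images (base64) and the key
tables into a single self-contained file.
"""

from __future__ import annotations

import base64
import html
import logging
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .annotation import AnnotationSet  # noqa: E402
from .grid import Ribogrid  # noqa: E402
from .summaries import MetageneProfile  # noqa: E402

log = logging.getLogger(__name__)


def _export_path(image_path: str | Path) -> Path:
    p = Path(image_path)
    return p.with_suffix(p.suffix + ".tsv") if p.suffix != ".tsv" else p


def _save(fig: plt.Figure, path: Path) -> None:
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_length_distribution(dist: pd.Series, out_png: str | Path) -> Path:
    out_png = Path(out_png)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(dist.index, dist.values, color="#4878A8", width=0.8)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("footprints")
    ax.set_title("Read length distribution")
    _save(fig, out_png)
    dist.rename("n_reads").to_frame().reset_index().to_csv(
        _export_path(out_png), sep="\t", index=False
    )
    return out_png


def plot_frame_proportions(
    frame_table: pd.DataFrame, out_png: str | Path
) -> Path:
    """Per-gene frame-0/1/2 proportions (covered genes only)."""
    out_png = Path(out_png)
    covered = frame_table[~frame_table["low_coverage"]].copy()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    if len(covered):
        data = [covered["p0"], covered["p1"], covered["p2"]]
        ax.boxplot(data, tick_labels=["frame 0", "frame +1", "frame +2"])
    ax.set_ylabel("proportion of footprints per gene")
    ax.set_ylim(0, 1)
    ax.set_title("Reading-frame proportions per gene")
    _save(fig, out_png)
    covered.to_csv(_export_path(out_png), sep="\t", index=False)
    return out_png


def plot_metagene(profile: MetageneProfile, out_png: str | Path) -> Path:
    out_png = Path(out_png)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    colors = np.take(["#4878A8", "#E1812C", "#3A923A"], profile.rel_positions % 3)
    ax.bar(profile.rel_positions, profile.counts, color=colors, width=1.0)
    ax.axvline(0, color="black", lw=0.8, ls="--")
    ax.set_xlabel(f"nt relative to {profile.anchor.replace('_', ' ')}")
    ax.set_ylabel("footprint 5' ends")
    ax.set_title("Metagene profile (colored by frame)")
    _save(fig, out_png)
    profile.to_frame().to_csv(_export_path(out_png), sep="\t", index=False)
    return out_png


def plot_ribogrid_heatmap(
    grid: Ribogrid,
    annotation: AnnotationSet | None = None,
    out_png: str | Path = "ribogrid.png",
    region: tuple[int, int] | None = None,
) -> Path:
    """Heatmap of one transcript's grid: x = 5' position, y = read length.

    Color is log1p(count); start/stop codon positions are marked when the
    annotation is supplied.  An all-zero grid renders as a blank heatmap.
    """
    out_png = Path(out_png)
    p1, p2 = region if region is not None else (0, grid.transcript_length - 1)
    if not (0 <= p1 <= p2 < grid.transcript_length):
        raise ValueError(f"region {region} outside transcript")
    sub = grid.counts[:, p1 : p2 + 1]
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.imshow(
        np.log1p(sub),
        aspect="auto",
        origin="lower",
        interpolation="nearest",
        extent=(p1 + 0.5, p2 + 1.5, grid.min_length - 0.5, grid.max_length + 0.5),
        cmap="viridis",
    )
    if annotation is not None and grid.transcript_id in annotation:
        t = annotation[grid.transcript_id]
        ax.axvline(t.cds_start + 1, color="white", lw=0.8, ls="--")
        ax.axvline(t.cds_end, color="red", lw=0.8, ls="--")
    ax.set_xlabel("5' position (1-based)")
    ax.set_ylabel("read length (nt)")
    ax.set_title(f"Ribogrid: {grid.transcript_id}")
    _save(fig, out_png)
    export = pd.DataFrame(
        sub,
        index=pd.RangeIndex(grid.min_length, grid.max_length + 1,
                            name="read_length"),
        columns=pd.RangeIndex(p1 + 1, p2 + 2, name="pos_1based"),
    )
    export.to_csv(_export_path(out_png), sep="\t")
    return out_png


def aggregate_start_anchored_grid(
    grids: Mapping[str, Ribogrid],
    annotation: AnnotationSet,
    window: int = 60,
) -> Ribogrid:
    """Sum grids over transcripts after aligning columns on the start codon.

    Column ``window`` of the result corresponds to the first base of the
    start codon; this is the aggregate view in which the length-dependent
    5' displacement and period-3 column structure are visible.
    """
    bounds = {(g.min_length, g.max_length) for g in grids.values()}
    if len(bounds) != 1:
        raise ValueError("mixed length bounds across grids")
    min_length, max_length = next(iter(bounds))
    agg = np.zeros((max_length - min_length + 1, 2 * window), dtype=np.int64)
    for tid, g in grids.items():
        s = annotation[tid].cds_start
        lo, hi = max(0, s - window), min(g.transcript_length, s + window)
        agg[:, (lo - s) + window : (hi - s) + window] += g.counts[:, lo:hi]
    return Ribogrid("start_anchored_aggregate", min_length, max_length, agg)


def plot_codon_feature(
    table: pd.DataFrame, out_png: str | Path, feature_name: str = "feature"
) -> Path:
    """Scatter of mean normalized codon density vs an external codon feature."""
    out_png = Path(out_png)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        table["feature"], table["mean_normalized_density"], s=14,
        color="#4878A8", alpha=0.8,
    )
    ax.set_xlabel(feature_name)
    ax.set_ylabel("mean normalized codon density")
    ax.set_title("Codon-specific density vs feature")
    _save(fig, out_png)
    table.to_csv(_export_path(out_png), sep="\t", index=False)
    return out_png


_REPORT_SECTIONS = (
    ("length_distribution", "Read length distribution"),
    ("frame_proportions", "Reading-frame proportions"),
    ("metagene", "Metagene profile"),
    ("ribogrid_heatmap", "Ribogrid heatmap"),
    ("codon_feature", "Codon density vs feature"),
)


def render_html_report(
    sample_name: str,
    plots: Mapping[str, str | Path],
    tables: Mapping[str, pd.DataFrame] | None = None,
    out_html: str | Path = "report.html",
    timestamp: str | None = None,
    metadata: Mapping[str, object] | None = None,
) -> Path:
    """Combine the plots and key tables into one self-contained HTML file.

    Images are embedded base64 so the file has no external references; a
    missing plot becomes a visible placeholder rather than an error.  Output
    is byte-stable for identical inputs when ``timestamp`` is pinned (or
    omitted).
    """
    out_html = Path(out_html)
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>ribogridkit report: {html.escape(sample_name)}</title>",
        "<style>body{font-family:sans-serif;max-width:1000px;margin:2em auto;}"
        "table{border-collapse:collapse;font-size:0.85em;}"
        "td,th{border:1px solid #ccc;padding:2px 8px;}"
        ".missing{color:#a33;border:1px dashed #a33;padding:1em;}</style>",
        "</head><body>",
        f"<h1>Sample: {html.escape(sample_name)}</h1>",
    ]
    meta_rows = dict(metadata or {})
    if timestamp is not None:
        meta_rows["generated"] = timestamp
    if meta_rows:
        parts.append("<table>")
        for k, v in meta_rows.items():
            parts.append(
                f"<tr><th>{html.escape(str(k))}</th>"
                f"<td>{html.escape(str(v))}</td></tr>"
            )
        parts.append("</table>")
    for key, title in _REPORT_SECTIONS:
        parts.append(f"<h2>{html.escape(title)}</h2>")
        path = plots.get(key)
        if path is not None and Path(path).exists():
            data = base64.b64encode(Path(path).read_bytes()).decode()
            parts.append(
                f"<img alt='{html.escape(title)}' "
                f"src='data:image/png;base64,{data}'/>"
            )
        else:
            parts.append(
                f"<div class='missing'>no data: {html.escape(title)} "
                "not available for this sample</div>"
            )
            log.warning("report %s: missing plot %s", sample_name, key)
    for name, df in (tables or {}).items():
        parts.append(f"<h2>{html.escape(name)}</h2>")
        parts.append(df.head(25).to_html(index=False, border=0))
    parts.append("</body></html>")
    out_html.write_text("".join(parts))
    return out_html
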
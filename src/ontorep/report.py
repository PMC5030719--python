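"""Repertoire figures and their machine-readable table twins.

Every figure type has a tabular counterpart (the tables are the tested
surface; images are optional renderings): repertoire histograms (gene
usage, CDR3 length and net charge, SHM, read length, status),
identity-divergence heat maps with optional overlay points, and
birthday-colored lineage trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .lineage import IdDivRecord
from .ontogeny import OntogenyTree
from .phylo import Node

log = logging.getLogger(__name__)

VARIABLES = (
    "v_gene_usage",
    "j_gene_usage",
    "d_gene_usage",
    "c_usage",
    "cdr3_len_aa",
    "v_divergence_pct",
    "read_length",
    "status",
    "cdr3_charge",
)

_VAR_COLUMN = {
    "v_gene_usage": "v_gene",
    "j_gene_usage": "j_gene",
    "d_gene_usage": "d_gene",
    "c_usage": "c_gene",
    "cdr3_len_aa": "cdr3_len_aa",
    "v_divergence_pct": "v_divergence_pct",
    "read_length": "length",
    "status": "status",
}


@dataclass
class HistogramSpec:
    variable: str
    subset: str = "all"  # all | functional | unique | custom
    bins: list | None = None
    custom_ids: set[str] = field(default_factory=set)
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.bins is not None and all(
            isinstance(b, (int, float)) for b in self.bins
        ):
            edges = list(self.bins)
            if any(b >= a for b, a in zip(edges[1:], edges)):
                raise ValueError("numeric bins must be strictly increasing")


def cdr3_charge(cdr3_aa: str) -> int:
    """Net charge of a CDR3 peptide: (#R + #K) - (#D + #E)."""
    return sum(cdr3_aa.count(a) for a in "RK") - sum(
        cdr3_aa.count(a) for a in "DE"
    )


def _subset(table: pd.DataFrame, spec: HistogramSpec) -> pd.DataFrame:
    if spec.subset == "all":
        return table
    if spec.subset == "functional":
        # V and J assigned, in-frame junction, no stop codons
        ok = (
            table["v_gene"].notna()
            & table["j_gene"].notna()
            & table["cdr3_aa"].notna()
            & table["status"].isin(["good", "unique"])
        )
        return table[ok]
    if spec.subset == "unique":
        return table[table["status"] == "unique"]
    if spec.subset == "custom":
        return table[table["read_id"].isin(spec.custom_ids)]
    raise ValueError(f"unknown subset {spec.subset!r}")


def tabulate_histogram(
    tables: pd.DataFrame | dict[str, pd.DataFrame],
    spec: HistogramSpec,
    image_path: str | None = None,
) -> pd.DataFrame:
    """Counts per bin/category per sample for one repertoire property."""
    if isinstance(tables, pd.DataFrame):
        tables = {"sample": tables}
    per_sample = {}
    for name, table in tables.items():
        sub = _subset(table, spec)
        if spec.variable == "cdr3_charge":
            values = sub["cdr3_aa"].dropna().map(cdr3_charge)
        else:
            values = sub[_VAR_COLUMN[spec.variable]].dropna()
        if spec.variable in ("v_gene_usage", "j_gene_usage", "d_gene_usage", "c_usage", "status"):
            counts = values.value_counts().sort_index()
        elif spec.bins is not None:
            binned = pd.cut(values, bins=spec.bins, right=False)
            counts = binned.value_counts().sort_index()
            counts.index = counts.index.astype(str)
        else:
            counts = values.astype(int).value_counts().sort_index()
        per_sample[name] = counts
    out = pd.DataFrame(per_sample).fillna(0).astype(int)
    out.index.name = spec.variable
    out = out.reset_index()
    if image_path:
        ax = out.set_index(spec.variable).plot.bar(figsize=(8, 4))
        ax.set_ylabel("count")
        ax.figure.tight_layout()
        ax.figure.savefig(image_path)
        plt.close(ax.figure)
    return out


# ---------------------------------------------------------------------------
# identity-divergence heat maps


def iddiv_heatmap(
    records: list[IdDivRecord],
    seed_name: str,
    bin_width: float = 1.0,
    overlay: set[str] | None = None,
    multi: dict[str, list[IdDivRecord]] | None = None,
    image_path: str | None = None,
) -> dict:
    """2-D binned counts over divergence (x) and identity-to-seed (y) on
    [0, 100]^2; overlay read ids become an explicit point list; in multi
    mode one grid per time point shares the axes."""
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    groups = multi if multi is not None else {"all": records}
    grids = {}
    points = []
    known = {r.read_id for recs in groups.values() for r in recs}
    for rid in overlay or set():
        if rid not in known:
            log.warning("overlay id %s not in id-div records; skipped", rid)
    for label, recs in groups.items():
        recs = [r for r in recs if seed_name in r.identity_pct]
        if not recs and records:
            raise KeyError(f"seed {seed_name!r} absent from records")
        x = np.array([r.divergence_pct for r in recs])
        y = np.array([r.identity_pct[seed_name] for r in recs])
        grid, _, _ = np.histogram2d(
            np.clip(x, 0, 100 - 1e-9), np.clip(y, 0, 100 - 1e-9), bins=(edges, edges)
        )
        grids[label] = grid
        if overlay:
            points.extend(
                (label, r.read_id, r.divergence_pct, r.identity_pct[seed_name])
                for r in recs
                if r.read_id in overlay
            )
    if image_path:
        fig, axes = plt.subplots(
            1, len(grids), figsize=(4 * len(grids), 4), squeeze=False,
            sharex=True, sharey=True,
        )
        for ax, (label, grid) in zip(axes[0], grids.items()):
            masked = np.ma.masked_equal(grid.T, 0)
            ax.pcolormesh(edges, edges, masked, cmap="viridis")
            ax.set_title(label)
            ax.set_xlabel("divergence from germline V (%)")
        axes[0][0].set_ylabel(f"identity to {seed_name} (%)")
        for label, rid, x, y in points:
            for ax, glabel in zip(axes[0], grids):
                if glabel == label:
                    ax.plot(x, y, "o", color="orange", ms=3)
        fig.tight_layout()
        fig.savefig(image_path)
        plt.close(fig)
    out = {"edges": edges, "grids": grids, "overlay_points": points}
    return out


# ---------------------------------------------------------------------------
# birthday trees


def _branch_color_labels(
    node: Node, birthdays: dict[str, str], order: dict[str, int]
) -> dict[int, str | None]:
    """Earliest descendant birthday for every node (None when no labeled
    leaf is below)."""
    out: dict[int, str | None] = {}

    def visit(n: Node) -> str | None:
        if n.is_leaf:
            lab = birthdays.get(n.name)
        else:
            labs = [visit(c) for c in n.children]
            labs = [l for l in labs if l is not None]
            lab = min(labs, key=order.__getitem__) if labs else None
        out[id(n)] = lab
        return lab

    visit(node)
    return out


def render_tree(
    tree: OntogenyTree,
    label_list: list[str] | None = None,
    collapse_list: list[str] | None = None,
    image_path: str | None = None,
) -> pd.DataFrame:
    """Birthday-colored tree rendering.

    Branches take the color of the earliest birthday among the leaves
    below them; requested nodes are labeled, requested clades drawn
    collapsed.  Returns the legend table (label -> color); the image is
    written when *image_path* is given.
    """
    labels = sorted(
        set(tree.birthdays.values()),
        key=list(dict.fromkeys(tree.birthdays.values())).index,
    )
    order = {lab: i for i, lab in enumerate(labels)}
    cmap = plt.get_cmap("viridis", max(len(labels), 1))
    colors = {lab: matplotlib.colors.to_hex(cmap(i)) for i, lab in enumerate(labels)}
    legend = pd.DataFrame(
        {"label": labels, "color": [colors[l] for l in labels]}
    )
    for name in label_list or []:
        try:
            tree.root.find(name)
        except KeyError:
            log.warning("label %s not in tree", name)
    if image_path:
        root = tree.root.copy()
        for name in collapse_list or []:
            try:
                node = root.find(name)
            except KeyError:
                log.warning("collapse target %s not in tree", name)
                continue
            node.children = []
            node.name = f"{name} (collapsed)"
        branch_lab = _branch_color_labels(root, tree.birthdays, order)
        ys: dict[int, float] = {}
        next_y = [0.0]

        def place(n: Node, x0: float):
            x = x0 + n.length
            if n.is_leaf:
                ys[id(n)] = next_y[0]
                next_y[0] += 1.0
            else:
                for c in n.children:
                    place(c, x)
                ys[id(n)] = np.mean([ys[id(c)] for c in n.children])
            return x

        fig, ax = plt.subplots(figsize=(7, max(3, 0.18 * len(root.leaves()))))

        def draw(n: Node, x0: float):
            x = x0 + n.length
            lab = branch_lab.get(id(n))
            color = colors.get(lab, "#888888")
            ax.plot([x0, x], [ys[id(n)], ys[id(n)]], color=color, lw=1.2)
            if not n.is_leaf:
                ylo = min(ys[id(c)] for c in n.children)
                yhi = max(ys[id(c)] for c in n.children)
                ax.plot([x, x], [ylo, yhi], color=color, lw=1.2)
                for c in n.children:
                    draw(c, x)
            if n.is_leaf or (label_list and n.name in label_list):
                ax.text(x, ys[id(n)], f" {n.name}", fontsize=5, va="center")

        place(root, 0.0)
        draw(root, 0.0)
        ax.set_yticks([])
        ax.set_xlabel("substitutions/site")
        fig.tight_layout()
        fig.savefig(image_path)
        plt.close(fig)
    return legend
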
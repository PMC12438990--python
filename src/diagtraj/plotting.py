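"""Sequence frequency/index plots and entropy bar charts.

Rendering is metadata-first: every plot writes a sidecar JSON describing
exactly what was drawn (bands, heights, labels), so plot contracts —
proportionality of band heights to counts, suppression of small cells — are
testable without image diffing.  Small-cell suppression is enforced before
anything reaches the canvas: sequences supported by fewer than five persons
are never rendered, and a stratum suppressed in full yields a placeholder
image carrying a notice.

State colors come from a fixed shipped palette so plots are comparable
across runs.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.patches as mpatches
import matplotlib.pyplot as plt
import pandas as pd

from .sequences import SequenceSet, sequence_frequency_table


def load_palette() -> dict[str, str]:
    """Fixed state->color mapping (21 distinct colors)."""
    ref = resources.files("diagtraj.data").joinpath("palette.json")
    return json.loads(ref.read_text())


def _write_sidecar(out_path: Path, meta: dict) -> Path:
    sidecar = out_path.with_suffix(out_path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return sidecar


def _placeholder(out_path: Path, title: str, meta: dict) -> dict:
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.text(0.5, 0.5, "all sequences suppressed (< 5 persons per sequence)",
            ha="center", va="center")
    ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(out_path)
    plt.close(fig)
    meta["placeholder"] = True
    _write_sidecar(out_path, meta)
    return meta


def _legend_for(states: set[str], palette: dict[str, str]):
    return [
        mpatches.Patch(color=palette[s], label=s)
        for s in sorted(states, key=lambda s: list(palette).index(s))
    ]


def plot_sequence_frequency(
    sset: SequenceSet, out_path: str | Path, min_count: int = 5
) -> dict:
    """Horizontal-band frequency plot: one band per displayed distinct
    sequence, band height proportional to its count, x-axis periods 1-10."""
    out_path = Path(out_path)
    palette = load_palette()
    table = sequence_frequency_table(sset, min_count=min_count)
    title = f"Sequence frequencies — {'|'.join(sset.label)}"
    meta = {
        "kind": "sequence_frequency",
        "stratum": list(sset.label),
        "n": len(sset),
        "min_count": min_count,
        "suppressed_count": table.suppressed_count,
        "suppressed_distinct": table.suppressed_distinct,
        "bands": [],
        "placeholder": False,
    }
    if table.displayed.empty:
        return _placeholder(out_path, title, meta)

    shown_total = int(table.displayed["count"].sum())
    n_periods = len(sset.sequences[0].states)
    fig, ax = plt.subplots(figsize=(9, 5))
    y = 0.0
    used_states: set[str] = set()
    for _, row in table.displayed.iterrows():
        states = row["sequence"].split(">")
        height = row["count"] / shown_total
        for k, state in enumerate(states):
            ax.add_patch(
                mpatches.Rectangle((k, y), 1.0, height, facecolor=palette[state],
                                   edgecolor="none")
            )
            used_states.add(state)
        meta["bands"].append(
            {
                "sequence": row["sequence"],
                "count": int(row["count"]),
                "height_fraction": height,
            }
        )
        y += height
    ax.set_xlim(0, n_periods)
    ax.set_ylim(0, 1)
    ax.set_xticks(range(n_periods + 1))
    ax.set_xlabel("12-month period")
    ax.set_ylabel("share of displayed sequences")
    ax.set_title(title)
    ax.legend(handles=_legend_for(used_states, palette), fontsize=7,
              loc="center left", bbox_to_anchor=(1.01, 0.5))
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    _write_sidecar(out_path, meta)
    return meta


def plot_sequence_index(
    sset: SequenceSet, out_path: str | Path, min_count: int = 5
) -> dict:
    """Index plot: one row per person, restricted to persons whose distinct
    sequence passes the suppression threshold."""
    out_path = Path(out_path)
    palette = load_palette()
    table = sequence_frequency_table(sset, min_count=min_count)
    displayed = set(table.displayed["sequence"])
    persons = [q for q in sset.sequences if ">".join(q.states) in displayed]
    title = f"Sequence index — {'|'.join(sset.label)}"
    meta = {
        "kind": "sequence_index",
        "stratum": list(sset.label),
        "n": len(sset),
        "n_rendered": len(persons),
        "min_count": min_count,
        "suppressed_count": table.suppressed_count,
        "placeholder": False,
    }
    if not persons:
        return _placeholder(out_path, title, meta)
    persons.sort(key=lambda q: q.states)
    n_periods = len(persons[0].states)
    fig, ax = plt.subplots(figsize=(9, 6))
    used_states: set[str] = set()
    for i, q in enumerate(persons):
        for k, state in enumerate(q.states):
            ax.add_patch(
                mpatches.Rectangle((k, i), 1.0, 1.0, facecolor=palette[state],
                                   edgecolor="none")
            )
            used_states.add(state)
    ax.set_xlim(0, n_periods)
    ax.set_ylim(0, len(persons))
    ax.set_xlabel("12-month period")
    ax.set_ylabel("person")
    ax.set_title(title)
    ax.legend(handles=_legend_for(used_states, palette), fontsize=7,
              loc="center left", bbox_to_anchor=(1.01, 0.5))
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    _write_sidecar(out_path, meta)
    return meta


def plot_entropy_bars(summary: pd.DataFrame, out_path: str | Path) -> dict:
    """Bar chart of mean entropy per stratum; suppressed strata omitted."""
    out_path = Path(out_path)
    shown = summary[~summary["suppressed"]]
    meta = {
        "kind": "entropy_bars",
        "bars": [
            {"stratum": r["stratum"], "mean_h": r["mean_h"], "n": int(r["n"])}
            for _, r in shown.iterrows()
        ],
        "n_suppressed_strata": int(summary["suppressed"].sum()),
        "placeholder": False,
    }
    if shown.empty:
        return _placeholder(out_path, "Mean normalized entropy", meta)
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(shown)), 4.5))
    ax.bar(shown["stratum"], shown["mean_h"], color="#4c72b0")
    ax.set_ylabel("mean normalized entropy")
    ax.set_title("Mean normalized entropy by stratum")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    _write_sidecar(out_path, meta)
    return meta
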
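"""Minimal figure rendering from the pipeline's source tables.

Every figure the pipeline supports is first written as a delimited source
table (screening, stratified, volcano, KM, histogram); these helpers turn
those tables into plain matplotlib renderings.  Styling is deliberately
minimal — the tables are the product, the plots are a convenience.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def forest_plot(screen_df: pd.DataFrame, path: str | Path,
                title: str = "") -> None:
    """Forest plot of ROR with 95% CI per drug (dashed line at ROR = 1)."""
    df = screen_df[~screen_df["excluded_low_count"]
                   & screen_df["ROR"].notna()].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.5 * max(len(df), 2) + 1))
    y = np.arange(len(df))[::-1]
    ax.errorbar(df["ROR"], y,
                xerr=[df["ROR"] - df["ROR_lo"], df["ROR_hi"] - df["ROR"]],
                fmt="o", color="k", capsize=3)
    ax.axvline(1.0, ls="--", color="grey")
    ax.set_yticks(y)
    labels = df["drug"]
    if "level" in df.columns and (df["level"] != "overall").any():
        labels = df["drug"] + " " + df["variable"] + "=" + df["level"]
    ax.set_yticklabels(labels)
    ax.set_xscale("log")
    ax.set_xlabel("ROR (95% CI)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def volcano_plot(volcano_df: pd.DataFrame, path: str | Path,
                 title: str = "") -> None:
    """Volcano plot: x = ln(ROR), y = -log10(p), point size = n11."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for (db,), sub in volcano_df.groupby(["database"]):
        ax.scatter(sub["x"], sub["y"], s=10 + 2 * sub["size"],
                   alpha=0.7, label=str(db))
    ax.axvline(0.0, ls="--", color="grey")
    ax.axhline(-np.log10(0.05), ls="--", color="grey")
    ax.set_xlabel("ln(ROR)")
    ax.set_ylabel("-log10(p)")
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(km_df: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Cumulative onset curves per database x drug."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for (db, drug), sub in km_df.groupby(["database", "drug"]):
        ax.step(sub["t_days"], sub["cum_pct"], where="post",
                label=f"{drug} ({db})")
    ax.set_xlabel("time to onset (days)")
    ax.set_ylabel("cumulative proportion of reports (%)")
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
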
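"""Summary figures: clustering strip plot, per-patient TKV trajectories,
and the pooled delta-eGFR scatter with group trendlines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_COLORS = {"responder": "tab:blue", "non-responder": "tab:red"}


def plot_delta_clusters(calls: pd.DataFrame, split_value: float,
                        path: str | Path) -> str:
    """Strip plot of per-patient growth-rate changes with the k-means split."""
    fig, ax = plt.subplots(figsize=(6, 3))
    for label, grp in calls.groupby("label"):
        ax.scatter(grp["delta"], np.zeros(len(grp)),
                   color=_COLORS.get(label, "gray"), label=label, alpha=0.8)
    ax.axvline(split_value, color="k", linestyle="--", lw=1,
               label=f"split = {split_value:.2f}")
    ax.set_xlabel("change in annual TKV growth rate (points/yr)")
    ax.set_yticks([])
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_patient_trajectory(scans: pd.DataFrame, treatment_start_age: float,
                            fits: pd.DataFrame, path: str | Path) -> str:
    """One patient's mean TKV per scan with the two fitted exponentials."""
    pts = scans.groupby("age_years")["tkv_ml"].mean()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(pts.index, pts.values, color="k", zorder=3)
    ax.axvline(treatment_start_age, color="gray", linestyle="--", lw=1)
    for _, row in fits.iterrows():
        rate, ref_age, tkv_ref = row["annual_rate"], row["ref_age"], row["tkv_at_ref_age"]
        ages = np.linspace(pts.index.min(), pts.index.max(), 100)
        mask = ages <= treatment_start_age if row["window"] == "pre" \
            else ages > treatment_start_age
        ax.plot(ages[mask],
                tkv_ref * (1 + rate / 100.0) ** (ages[mask] - ref_age),
                label=f"{row['window']}: {rate:.1f} %/yr")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("TKV (mL)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_egfr_trajectories(labs: pd.DataFrame, labels: pd.Series,
                           comparison, path: str | Path) -> str:
    """Pooled delta-eGFR scatter (4-month bins) with per-group trendlines."""
    df = labs.copy()
    df["group"] = df["patient_id"].map(labels)
    df["bin"] = (np.round(df["months_since_start"] / 4.0) * 4.0).clip(lower=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, grp in df.groupby("group"):
        ax.scatter(grp["bin"] / 12.0, grp["delta_egfr"], s=8, alpha=0.35,
                   color=_COLORS.get(g, "gray"), label=None)
    years = np.linspace(0, df["months_since_start"].max() / 12.0, 50)
    for g, gs in comparison.slopes.items():
        ax.plot(years, gs.slope * years, color=_COLORS.get(g, "gray"),
                label=f"{g}: {gs.slope:.2f}/yr")
    pooled = np.mean([gs.slope for gs in comparison.slopes.values()])
    ax.plot(years, pooled * years, color="k", lw=1, label=f"all: {pooled:.2f}/yr")
    ax.set_xlabel("years since treatment start")
    ax.set_ylabel("change in eGFR (mL/min/1.73 m$^2$)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
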
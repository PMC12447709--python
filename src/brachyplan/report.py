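"""DVH reporting: cumulative curves, metric tables, CSV and figure output."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dvh import METRIC_ORDER, compute_plan_metrics, dose_from_dwell
from .phantom import CTV_IR, PatientCase, STRUCTURE_NAMES


def dvh_curves(
    case: PatientCase, d: np.ndarray, max_dose_pct: float = 300.0, n_points: int = 151
) -> pd.DataFrame:
    """Cumulative DVH per structure: volume %% vs dose %% of prescription.

    Target structures are normalized to their own prescription; OARs to the
    high-risk prescription.  Rows: structure x dose-grid point.
    """
    if case.dij is None:
        raise ValueError("case has no dose-influence matrices")
    levels = np.linspace(0.0, max_dose_pct, n_points)
    frames = []
    for name in STRUCTURE_NAMES:
        rx = case.prescriptions.rx_ir if name == CTV_IR else case.prescriptions.rx_hr
        dose = dose_from_dwell(case.dij.matrices[name], d)
        vol = 100.0 * np.mean(dose[None, :] >= (levels[:, None] / 100.0 * rx), axis=1)
        frames.append(
            pd.DataFrame({"structure": name, "dose_pct": levels, "volume_pct": vol})
        )
    return pd.concat(frames, ignore_index=True)


def dvh_report(
    case: PatientCase,
    plans: dict[str, np.ndarray],
    out_dir: str | Path,
    styles: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write DVH curves (CSV + figure) and a metric table for named plans."""
    if not plans:
        raise ValueError("at least one plan is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_dwells = case.dij.n_dwells if case.dij else None
    for name, d in plans.items():
        if len(d) != n_dwells:
            raise ValueError(f"plan {name!r} has {len(d)} dwells; expected {n_dwells}")

    curve_frames, metric_rows = [], []
    for name, d in plans.items():
        c = dvh_curves(case, d)
        c.insert(0, "plan", name)
        curve_frames.append(c)
        m = compute_plan_metrics(case, d)
        metric_rows.append({"plan": name, **dict(zip(METRIC_ORDER, m.as_vector()))})
    curves = pd.concat(curve_frames, ignore_index=True)
    metrics = pd.DataFrame(metric_rows)

    curves_path = out_dir / f"{case.id}_dvh.csv"
    metrics_path = out_dir / f"{case.id}_metrics.csv"
    fig_path = out_dir / f"{case.id}_dvh.png"
    curves.to_csv(curves_path, index=False)
    metrics.to_csv(metrics_path, index=False)

    fig, ax = plt.subplots(figsize=(8, 5))
    cmap = plt.get_cmap("tab10")
    line_styles = {name: (styles or {}).get(name, ls) for name, ls in
                   zip(plans, ["-", "--", ":", "-."] * 5)}
    for si, sname in enumerate(STRUCTURE_NAMES):
        for pname in plans:
            sub = curves[(curves.structure == sname) & (curves.plan == pname)]
            ax.plot(sub.dose_pct, sub.volume_pct, line_styles[pname],
                    color=cmap(si % 10),
                    label=f"{sname} ({pname})" if si < 2 else None, lw=1.0)
    for level in (100.0, 150.0, 200.0):
        ax.axvline(level, color="grey", lw=0.6, alpha=0.6)
    ax.set_xlabel("dose (% of prescription)")
    ax.set_ylabel("volume (%)")
    ax.set_title(f"DVH — {case.id}")
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    return {"curves": curves_path, "metrics": metrics_path, "figure": fig_path}
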
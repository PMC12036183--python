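"""Post-hoc figures: force-displacement and stress-strain curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import StressStrainCurve
from .controller import ExperimentLog

__all__ = ["plot_force_displacement", "plot_stress_strain"]


def plot_force_displacement(log: ExperimentLog, path: str | Path) -> Path:
    """Force (mN) against actuator displacement (mm), one point per step."""
    pos_mm = np.array([r.position_nm for r in log.records]) / 1e6
    force_mN = np.array([r.force_uN for r in log.records]) / 1e3
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(pos_mm, force_mN, marker=".", lw=1)
    ax.set_xlabel("actuator displacement (mm)")
    ax.set_ylabel("force (mN)")
    ax.set_title(f"{log.start_label} — {log.status}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_stress_strain(curve: StressStrainCurve, path: str | Path,
                       region: tuple[int, int] | None = None) -> Path:
    """Stress (MPa) against strain (%), optionally marking the linear region."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.strain_pct, curve.stress_MPa, marker=".", lw=1)
    if region is not None:
        a, b = region
        ax.plot(curve.strain_pct[a:b + 1], curve.stress_MPa[a:b + 1],
                lw=2, label="linear region")
        ax.legend()
    ax.set_xlabel("strain (%)")
    ax.set_ylabel("stress (MPa)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
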
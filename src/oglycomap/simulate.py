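"""Synthetic fixtures: calibration ladders, peak lists, sulfation kinetics.

Every pipeline stage can be exercised without instrument data. The retention
model per column is affine in GU (monotone, hence trivially invertible):
amide defaults to ``5 + 1.2*GU`` min, C30 to ``3 + 2.0*GU`` min — arbitrary
but fixed. A mixture specification names map structures with molar
fractions; simulated peaks sit at the mapped GU plus Gaussian noise, with
areas proportional to molar fraction times multiplicative noise. All
randomness flows from a single seed.

The GlcNAc6ST-1 branch-preference experiment is emulated as two-site
first-order parallel kinetics on a substrate with one beta1-6 and one
beta1-3 terminal GlcNAc: with preference ratio ``r`` and overall rate ``k``,
the 6-arm is sulfated at rate ``k*r/(1+r)`` and the 3-arm at ``k/(1+r)``;
only mono-sulfated products form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .calibration import GUCalibration, fit_calibration
from .profiling import Peak
from .reference_map import MapEntry, find_entry

__all__ = [
    "RetentionModel",
    "MixtureSpec",
    "DEFAULT_RETENTION_MODELS",
    "simulate_ladder",
    "simulate_calibrations",
    "simulate_peaklists",
    "fraction_label",
    "simulate_sulfation_timecourse",
    "fit_sulfation_kinetics",
]


@dataclass(frozen=True)
class RetentionModel:
    """Affine GU -> retention time map for one column."""

    intercept_min: float
    min_per_gu: float

    def rt(self, gu: float) -> float:
        return self.intercept_min + self.min_per_gu * gu


DEFAULT_RETENTION_MODELS: Dict[str, RetentionModel] = {
    "amide": RetentionModel(5.0, 1.2),
    "C30": RetentionModel(3.0, 2.0),
}


@dataclass(frozen=True)
class MixtureSpec:
    """Ground truth for a simulated glycan mixture."""

    components: Tuple[Tuple[str, float], ...]  # (structure text, molar fraction)
    sigma_gu: float = 0.0
    area_noise: float = 0.0
    seed: int = 0
    retention: Dict[str, RetentionModel] = field(
        default_factory=lambda: dict(DEFAULT_RETENTION_MODELS)
    )

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"molar fractions sum to {total}, not 1")
        if self.sigma_gu < 0 or self.area_noise < 0:
            raise ValueError("noise levels must be non-negative")


def fraction_label(charge: int) -> str:
    """Mono-Q fraction naming: N (neutral), MS (mono-), DS (di-anionic)."""
    return {0: "N", 1: "MS", 2: "DS"}.get(charge, f"Q{charge}")


def simulate_ladder(
    model: RetentionModel, n_max: int = 20
) -> List[Tuple[int, float]]:
    """Noise-free isomalto-oligosaccharide ladder (DP 1..n_max) for a column."""
    return [(n, model.rt(float(n))) for n in range(1, n_max + 1)]


def simulate_calibrations(
    retention: Optional[Dict[str, RetentionModel]] = None, n_max: int = 20
) -> Dict[str, GUCalibration]:
    retention = dict(DEFAULT_RETENTION_MODELS) if retention is None else retention
    return {
        col: fit_calibration(simulate_ladder(model, n_max), column=col)
        for col, model in retention.items()
    }


def simulate_peaklists(
    spec: MixtureSpec, entries: Sequence[MapEntry], base_area: float = 1e5
) -> List[Peak]:
    """Emit per-component C30 and amide peaks with Mono-Q charge labels.

    Every component must exist in the reference map; its true GU coordinates
    are the mapped ones. Deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    peaks: List[Peak] = []
    for i, (text, fraction) in enumerate(spec.components):
        entry = find_entry(entries, text)
        if entry is None:
            raise ValueError(f"structure not in reference map: {text!r}")
        gid = f"g{i:03d}"
        label = fraction_label(entry.charge_class)
        for column, gu_true in (("C30", entry.gu_c30), ("amide", entry.gu_amide)):
            gu_obs = gu_true + rng.normal(0.0, spec.sigma_gu) if spec.sigma_gu else gu_true
            rt = spec.retention[column].rt(gu_obs)
            noise = rng.normal(0.0, spec.area_noise) if spec.area_noise else 0.0
            area = base_area * fraction * max(0.0, 1.0 + noise)
            peaks.append(
                Peak(
                    group_id=gid,
                    fraction=label,
                    charge=entry.charge_class,
                    column=column,
                    rt_min=rt,
                    area=area,
                )
            )
    return peaks


def peaks_to_csv(peaks: Sequence[Peak], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "group_id": p.group_id,
                "fraction": p.fraction,
                "charge": p.charge,
                "column": p.column,
                "rt_min": p.rt_min,
                "area": p.area,
                "flag": p.flag,
            }
            for p in peaks
        ]
    ).to_csv(path, index=False)


def simulate_sulfation_timecourse(
    r: float,
    k: float,
    times: Sequence[float],
    s0: float = 1.0,
    noise: float = 0.0,
    seed: Optional[int] = None,
) -> Dict[str, np.ndarray]:
    """Amounts of substrate and the two mono-sulfated products over time.

    ``product_6`` is the beta1-6-arm product (the preferred site for r > 1),
    ``product_3`` the beta1-3-arm product. Optional multiplicative Gaussian
    noise emulates peak-integration error.
    """
    if r <= 0 or k <= 0 or s0 <= 0:
        raise ValueError("r, k and s0 must be positive")
    t = np.asarray(times, dtype=float)
    decay = np.exp(-k * t)
    substrate = s0 * decay
    converted = s0 * (1.0 - decay)
    product_6 = converted * r / (1.0 + r)
    product_3 = converted / (1.0 + r)
    out = {"t": t, "substrate": substrate, "product_6": product_6, "product_3": product_3}
    if noise > 0:
        rng = np.random.default_rng(seed)
        for key in ("substrate", "product_6", "product_3"):
            out[key] = np.clip(out[key] * (1.0 + rng.normal(0.0, noise, t.shape)), 0, None)
    return out


def fit_sulfation_kinetics(
    times: Sequence[float],
    product_6: Sequence[float],
    product_3: Sequence[float],
    substrate: Optional[Sequence[float]] = None,
    s0: float = 1.0,
) -> Tuple[float, float]:
    """Least-squares recovery of (preference ratio r, overall rate k)."""
    t = np.asarray(times, dtype=float)
    p6 = np.asarray(product_6, dtype=float)
    p3 = np.asarray(product_3, dtype=float)
    sub = None if substrate is None else np.asarray(substrate, dtype=float)

    def residuals(theta):
        log_r, log_k = theta
        model = simulate_sulfation_timecourse(np.exp(log_r), np.exp(log_k), t, s0=s0)
        res = [model["product_6"] - p6, model["product_3"] - p3]
        if sub is not None:
            res.append(model["substrate"] - sub)
        return np.concatenate(res)

    fit = least_squares(residuals, x0=[0.0, np.log(0.05)])
    return float(np.exp(fit.x[0])), float(np.exp(fit.x[1]))
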
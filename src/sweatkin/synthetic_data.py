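"""Synthetic hemodialysis cohorts with paired pre/post blood–sweat records.

The clinical dataset the transport model was validated on is not public, so
this generator emulates its statistical structure: per patient a
pre-dialysis blood urea (lognormal, median 20 mmol/L), a urea reduction
ratio (Beta, mean 0.7) giving the post-dialysis value (cohort mean ≈ 6.4
mmol/L), per-timepoint active-transport rates drawn around the published
medians (0.51 pre, 0.21 post, IQR→SD by /1.35), a residual kidney function
(GFR, uniform 2–12 mL/min/1.73 m²) and a normalized sweat velocity
(uniform 1–4).  Sweat concentrations are produced by the forward transport
model itself plus multiplicative measurement noise, and a configurable
fraction of patients has missing sweat values (emulating insufficient
collection volume).  Fully seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import NumericalError, SimulationGrid, simulate
from .params import ModelParameters


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a synthetic dialysis cohort."""

    n_patients: int = 32
    pre_blood_median: float = 20.0  # mmol/L, lognormal median
    pre_blood_log_sd: float = 0.35
    urr_mean: float = 0.7  # urea reduction ratio, Beta-distributed
    urr_concentration: float = 20.0  # Beta a+b; sd ≈ 0.10 at the default
    S_pre_mean: float = 0.51  # mmol L⁻¹ s⁻¹, truncated normal
    S_pre_sd: float = 0.08  # ≈ IQR 0.11 / 1.35
    S_post_mean: float = 0.21
    S_post_sd: float = 0.045  # ≈ IQR 0.06 / 1.35
    sweat_noise_cv: float = 0.05  # multiplicative measurement noise
    gfr_lo: float = 2.0
    gfr_hi: float = 12.0
    sweat_velocity_lo: float = 1.0
    sweat_velocity_hi: float = 4.0
    missing_sweat_fraction: float = 0.2
    seed: int = 0
    s_mode: str = "gland_source"
    pressure_mode: str = "fixed"

    def validate(self) -> list[str]:
        bad = []
        for name in ("pre_blood_median", "pre_blood_log_sd", "urr_concentration",
                     "S_pre_mean", "S_pre_sd", "S_post_mean", "S_post_sd"):
            if not getattr(self, name) > 0:
                bad.append(f"{name} must be positive")
        if not 0 < self.urr_mean < 1:
            bad.append("urr_mean must lie in (0, 1)")
        for name in ("sweat_noise_cv", "missing_sweat_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                bad.append(f"{name} must lie in [0, 1]")
        if self.n_patients < 1:
            bad.append("n_patients must be >= 1")
        return bad


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:  # truncate at 0 by redraw
        batch = rng.normal(mean, sd, n - filled)
        batch = batch[batch > 0]
        out[filled : filled + batch.size] = batch
        filled += batch.size
    return out


def generate_cohort(
    spec: CohortSpec | None = None,
    params: ModelParameters | None = None,
    grid: SimulationGrid | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a paired pre/post cohort and its ground truth.

    Returns ``(samples, truth)``: *samples* matches the estimator's input
    schema (``sample_id, timepoint, sweat_urea_mmol_per_L,
    blood_urea_mmol_per_L, gfr, sweat_velocity_norm``) with 2 rows per
    patient; *truth* records the noise-free sweat value and the true
    active-transport rate per row.  Patients whose forward simulation fails
    are redrawn (at most 10 retries each, logged in ``truth.attrs``).
    """
    spec = spec or CohortSpec()
    problems = spec.validate()
    if problems:
        raise ValueError("invalid cohort spec: " + "; ".join(problems))
    params = params or ModelParameters()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_patients
    a = spec.urr_mean * spec.urr_concentration
    b = (1 - spec.urr_mean) * spec.urr_concentration

    sample_rows: list[dict] = []
    truth_rows: list[dict] = []
    redraws = 0
    for pid in range(n):
        for _attempt in range(10):
            pre_blood = float(np.exp(rng.normal(np.log(spec.pre_blood_median),
                                                spec.pre_blood_log_sd)))
            urr = float(rng.beta(a, b))
            post_blood = pre_blood * (1.0 - urr)
            gfr = float(rng.uniform(spec.gfr_lo, spec.gfr_hi))
            s_pre = float(_trunc_normal(rng, spec.S_pre_mean, spec.S_pre_sd, 1)[0])
            s_post = float(_trunc_normal(rng, spec.S_post_mean, spec.S_post_sd, 1)[0])
            u_pre = float(rng.uniform(spec.sweat_velocity_lo, spec.sweat_velocity_hi))
            u_post = float(rng.uniform(spec.sweat_velocity_lo, spec.sweat_velocity_hi))
            try:
                entries = []
                for tp, blood, s, u_n in (
                    ("pre", pre_blood, s_pre, u_pre),
                    ("post", post_blood, s_post, u_post),
                ):
                    theta = params.replace(S=s, u_sweat_n=u_n)
                    res = simulate(blood, theta, grid,
                                   pressure_mode=spec.pressure_mode,
                                   s_mode=spec.s_mode)
                    noise = 1.0 + rng.normal(0.0, spec.sweat_noise_cv)
                    entries.append((tp, blood, s, u_n, gfr,
                                    res.C_sweat, max(res.C_sweat * noise, 0.0)))
            except NumericalError:
                redraws += 1
                continue
            break
        else:
            raise RuntimeError(f"patient {pid}: simulation failed after 10 redraws")

        for tp, blood, s, u_n, gfr_v, sweat_true, sweat_obs in entries:
            sample_rows.append({
                "sample_id": f"P{pid:03d}",
                "timepoint": tp,
                "sweat_urea_mmol_per_L": sweat_obs,
                "blood_urea_mmol_per_L": blood,
                "gfr": gfr_v,
                "sweat_velocity_norm": u_n,
            })
            truth_rows.append({
                "sample_id": f"P{pid:03d}",
                "timepoint": tp,
                "true_blood_urea_mmol_per_L": blood,
                "true_S": s,
                "true_sweat_urea_mmol_per_L": sweat_true,
            })

    samples = pd.DataFrame(sample_rows)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["redraws"] = redraws

    # missing sweat values: whole patients, emulating insufficient volume
    n_missing = int(round(spec.missing_sweat_fraction * n))
    if n_missing:
        missing_ids = rng.choice(n, size=n_missing, replace=False)
        mask = samples["sample_id"].isin([f"P{i:03d}" for i in missing_ids])
        samples.loc[mask, "sweat_urea_mmol_per_L"] = np.nan
    return samples, truth
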
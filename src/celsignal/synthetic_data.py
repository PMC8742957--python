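"""Seeded generators for every input the signaling pipeline consumes.

The forward model mirrors the statistical structure the analysis assumes:

* **Cohort scores** are drawn from a K-component univariate normal mixture.
  The default 3-component spec uses the published right-most component
  (weight 0.48, mean 446, SD 195 signaling units); the two lower components
  are package defaults chosen to sit well below the 250-unit cutoff and are
  configuration, not published values.

* **Well traces** follow a rise-then-decay impedance kernel
  ``k(t) = (1 - exp(-t/tau_r)) * exp(-t/tau_d)`` scaled so that the
  per-minute sum of the noiseless treated-minus-control difference over the
  240-minute window equals the well's effective amplitude ``A_eff`` exactly.
  ``A_eff`` is the patient's pathway capacity scaled by agonist receptor
  occupancy (median-effect form) and by per-drug modulation factors.

* **Drug action** uses single-site occupancy ``fa(d) = d^m / (d^m + Dm^m)``
  with a signed per-pathway coupling ``X[d][p]``: the multiplier applied to
  pathway ``p`` is ``1 - fa(d) * X[d][p]``.  ``X = 1`` is a full on-target
  block at saturation, ``0 < X < 1`` partial cross-talk, and ``X < 0``
  enhancement (the multiplier exceeds 1, producing the negative
  percent-inhibition phenomenon seen when feedback is released).

* **Combination surfaces** are Loewe-additive at interaction ``alpha = 0``
  and deviate through a single product term on normalized doses, so a
  downstream combination-index analysis must return CI = 1 on additive
  surfaces, CI < 1 for ``alpha > 0`` and CI > 1 for ``alpha < 0``.

* **Xenograft volumes** grow exponentially, ``V(t) = V0 exp(g (1-e) t)``,
  with mean-preserving lognormal noise; ``e`` is the arm's treatment effect.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError
from .plate_io import (
    DEFAULT_AGONIST_DOSE_M,
    PATHWAYS,
    Antagonist,
    ImpedanceTrace,
    PlateLayout,
    WellCondition,
)

SCORING_WINDOW_MIN = 240


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    """K-component univariate normal mixture (signaling units)."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        mu = np.asarray(self.means, float)
        sd = np.asarray(self.sds, float)
        if not (w.size == mu.size == sd.size) or w.size == 0:
            raise ValidationError("weights, means, sds must have equal nonzero length")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must be positive and sum to 1")
        if np.any(sd <= 0):
            raise ValidationError("sds must be positive")
        object.__setattr__(self, "weights", tuple(w))
        object.__setattr__(self, "means", tuple(mu))
        object.__setattr__(self, "sds", tuple(sd))

    @property
    def k(self) -> int:
        return len(self.weights)


#: Default cohort mixture.  Component 3 is the published right-most
#: component (0.48, 446, 195).  Components 1-2 are synthetic defaults with
#: means well below the 250-unit cutoff, keeping the model false-positive
#: rate at that cutoff below 1% and the top two component means more than
#: four SDs apart.
DEFAULT_COHORT_MIXTURE = MixtureSpec(
    weights=(0.33, 0.19, 0.48),
    means=(40.0, 130.0, 446.0),
    sds=(35.0, 55.0, 195.0),
)


def median_effect_fa(dose, dm: float, m: float):
    """Fractional occupancy/effect ``d^m / (d^m + Dm^m)``; fa(Dm) = 0.5."""
    if dm <= 0 or m <= 0:
        raise ValidationError("median-effect parameters Dm, m must be > 0")
    d = np.asarray(dose, float)
    with np.errstate(divide="ignore"):
        r = np.power(d / dm, m)
    out = r / (1.0 + r)
    return float(out) if np.isscalar(dose) else out


@dataclass(frozen=True)
class DrugSpec:
    """An antagonist: single-site occupancy plus signed pathway couplings.

    ``effects[p]`` maps occupancy to the modulation of pathway ``p``:
    1 = full on-target inhibition at saturation, negative = enhancement.
    Pathways absent from ``effects`` are untouched by the drug.
    """

    name: str
    dm_molar: float
    m: float
    effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.dm_molar <= 0 or self.m <= 0:
            raise ValidationError(f"drug {self.name}: Dm and m must be > 0")
        bad = set(self.effects) - set(PATHWAYS)
        if bad:
            raise ValidationError(f"drug {self.name}: unknown pathways {sorted(bad)}")
        object.__setattr__(self, "effects", dict(self.effects))

    def occupancy(self, dose_molar: float) -> float:
        return median_effect_fa(dose_molar, self.dm_molar, self.m)


#: Default antagonist panel.  Potencies follow the reported live-cell IC50s
#: (tepotinib 14.7 nM on HGF signaling, neratinib 4.81 nM on HER signaling,
#: erlotinib and tucatinib as HER1-/HER2-selective comparators); slopes and
#: couplings are synthetic defaults.
DEFAULT_DRUGS: Mapping[str, DrugSpec] = {
    "tepotinib": DrugSpec("tepotinib", 14.7e-9, 1.2, {"cMet": 1.0}),
    "neratinib": DrugSpec("neratinib", 4.81e-9, 1.2,
                          {"HER1": 1.0, "HER2": 1.0, "HER3_4": 1.0}),
    "erlotinib": DrugSpec("erlotinib", 30e-9, 1.0, {"HER1": 1.0}),
    "tucatinib": DrugSpec("tucatinib", 333e-9, 1.0, {"HER2": 1.0}),
}

#: Default agonist potencies: with the standard assay doses (3 nM NRG1b,
#: 0.3 nM EGF, 0.08 nM HGF) receptor occupancy is 0.9, i.e. the standard
#: dose is approximately the EC90.
DEFAULT_AGONIST_POTENCY: Mapping[str, tuple[float, float]] = {
    agonist: (dose / 9.0, 1.0) for agonist, dose in DEFAULT_AGONIST_DOSE_M.items()
}


@dataclass(frozen=True)
class PatientProfile:
    """Per-patient generative parameters.

    ``capacity[p]`` is the expected full-window score at saturating agonist
    (signaling units); ``tau_rise``/``tau_decay`` shape the impedance
    kinetics (minutes); ``noise_sd`` is additive Gaussian noise per reading
    (Cell Index units); ``her2_split`` is the fraction of the HER2
    heterodimer signal carried by the NRG1b arm; ``crosstalk[d][p]``
    overrides the drug panel's coupling for this patient.
    """

    patient_id: str
    capacity: Mapping[str, float]
    tau_rise: float = 15.0
    tau_decay: float = 600.0
    noise_sd: float = 0.05
    baseline_ci: float = 1.0
    her2_split: float = 0.5
    crosstalk: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValidationError("tau_rise and tau_decay must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        cap = {p: float(self.capacity.get(p, 0.0)) for p in PATHWAYS}
        if not all(np.isfinite(v) for v in cap.values()):
            raise ValidationError("capacities must be finite")
        if not (0.0 <= self.her2_split <= 1.0):
            raise ValidationError("her2_split must be in [0, 1]")
        object.__setattr__(self, "capacity", cap)
        object.__setattr__(
            self, "crosstalk", {d: dict(m) for d, m in self.crosstalk.items()}
        )


# ---------------------------------------------------------------------------
# cohort scores
# ---------------------------------------------------------------------------

def generate_cohort_scores(
    spec: MixtureSpec, n: int, seed: int | None = None, pathway: str = "cMet"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw ``n`` scores from the mixture.

    Returns the cohort score table (patient_id, pathway, score) and the
    true component label of each draw (0-based), for recovery tests.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if pathway not in PATHWAYS:
        raise ValidationError(f"unknown pathway {pathway!r}")
    rng = np.random.default_rng(seed)
    labels = rng.choice(spec.k, size=n, p=spec.weights)
    mu = np.asarray(spec.means)[labels]
    sd = np.asarray(spec.sds)[labels]
    scores = rng.normal(mu, sd)
    df = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "pathway": pathway,
        "score": scores,
    })
    return df, labels


# ---------------------------------------------------------------------------
# traces and plates
# ---------------------------------------------------------------------------

def kinetic_kernel(t, tau_rise: float, tau_decay: float):
    """Rise-then-decay impedance response shape."""
    t = np.asarray(t, float)
    return (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)


def _kernel_norm(tau_rise: float, tau_decay: float) -> float:
    # per-minute sum over the inclusive 0..240 grid, so that the noiseless
    # score of a well with amplitude A_eff is exactly A_eff
    grid = np.arange(SCORING_WINDOW_MIN + 1, dtype=float)
    return float(kinetic_kernel(grid, tau_rise, tau_decay).sum())


def _ligand_contributions(
    profile: PatientProfile, agonist: str, her2_blocked: bool
) -> list[tuple[str, str, float]]:
    """(pathway, driving ligand, full-occupancy amplitude) triples."""
    cap = profile.capacity
    split = profile.her2_split
    parts: list[tuple[str, str, float]] = []
    if agonist in ("NRG1b", "cocktail"):
        parts.append(("HER3_4", "NRG1b", cap["HER3_4"]))
        if not her2_blocked:
            parts.append(("HER2", "NRG1b", split * cap["HER2"]))
    if agonist in ("EGF", "cocktail"):
        parts.append(("HER1", "EGF", cap["HER1"]))
        if not her2_blocked:
            parts.append(("HER2", "EGF", (1.0 - split) * cap["HER2"]))
    if agonist in ("HGF", "cocktail"):
        parts.append(("cMet", "HGF", cap["cMet"]))
    return parts


def well_amplitude(
    profile: PatientProfile,
    condition: WellCondition,
    drugs: Mapping[str, DrugSpec] = DEFAULT_DRUGS,
) -> float:
    """Effective noiseless full-window score ``A_eff`` of one well.

    Sums pathway contributions scaled by the driving ligand's receptor
    occupancy and by the product over antagonists of
    ``1 - occupancy_d * X[d][p]`` (clamped at zero from below; values above
    1 encode enhancement).  Cocktail wells stimulate every ligand arm at
    its standard assay dose.
    """
    agonist = condition.agonist
    if agonist is None:
        return 0.0
    total = 0.0
    for pathway, ligand, amp in _ligand_contributions(
            profile, agonist, condition.her2_blocked):
        dm, m = DEFAULT_AGONIST_POTENCY[ligand]
        if agonist == "cocktail" or condition.agonist_dose_molar is None:
            dose = DEFAULT_AGONIST_DOSE_M[ligand]
        else:
            dose = condition.agonist_dose_molar
        occ = median_effect_fa(dose, dm, m)
        mult = 1.0
        for ant in condition.antagonists:
            if ant.drug not in drugs:
                raise ValidationError(f"unknown drug {ant.drug!r} in condition")
            spec = drugs[ant.drug]
            coupling = profile.crosstalk.get(ant.drug, {}).get(
                pathway, spec.effects.get(pathway, 0.0))
            mult *= max(0.0, 1.0 - spec.occupancy(ant.dose_molar) * coupling)
        total += amp * occ * mult
    return total


def generate_trace(
    profile: PatientProfile,
    condition: WellCondition,
    window_min: float = SCORING_WINDOW_MIN,
    dt_min: float = 1.0,
    seed: int | None = None,
    well_id: str | None = None,
    drugs: Mapping[str, DrugSpec] = DEFAULT_DRUGS,
) -> ImpedanceTrace:
    """Simulate one well's Cell Index trace.

    ``cell_index(t) = baseline + A_eff * k(t)/Z + N(0, noise_sd)`` where
    ``Z`` normalizes the kernel's per-minute sum over the 240-min window.
    Control (C) wells have ``A_eff = 0``.
    """
    if dt_min <= 0:
        raise ValidationError("dt_min must be > 0")
    if window_min < SCORING_WINDOW_MIN:
        raise ValidationError(f"window must cover {SCORING_WINDOW_MIN} min")
    rng = np.random.default_rng(seed)
    a_eff = well_amplitude(profile, condition, drugs)
    t = np.arange(0.0, window_min + dt_min / 2, dt_min)
    z = _kernel_norm(profile.tau_rise, profile.tau_decay)
    ci = profile.baseline_ci + a_eff * kinetic_kernel(
        t, profile.tau_rise, profile.tau_decay) / z
    if profile.noise_sd > 0:
        ci = ci + rng.normal(0.0, profile.noise_sd, size=t.size)
    wid = well_id or f"{condition.patient_id}:{condition.condition_code}:{condition.replicate}"
    return ImpedanceTrace(wid, t, ci)


def generate_plate(
    profile: PatientProfile,
    layout: PlateLayout,
    seed: int | None = None,
    window_min: float = SCORING_WINDOW_MIN,
    dt_min: float = 1.0,
    drugs: Mapping[str, DrugSpec] = DEFAULT_DRUGS,
) -> list[ImpedanceTrace]:
    """Simulate every well of ``layout`` belonging to this patient.

    Replicate wells differ only by noise (independent child seeds, spawned
    in sorted well order for determinism).
    """
    well_ids = sorted(
        w for w, c in layout.wells.items() if c.patient_id == profile.patient_id
    )
    if not well_ids:
        raise ValidationError(f"layout has no wells for patient {profile.patient_id}")
    children = np.random.SeedSequence(seed).spawn(len(well_ids))
    traces = []
    for well_id, child in zip(well_ids, children):
        cond = layout.wells[well_id]
        traces.append(
            generate_trace(profile, cond, window_min, dt_min,
                           seed=child, well_id=well_id, drugs=drugs)
        )
    return traces


def default_plate_layout(patient_id: str, n_replicates: int = 2) -> PlateLayout:
    """Standard six-condition scheme (C, CF1, CDF1, CF2, CDF2, CF3)."""
    wells = {}
    codes = ["C", "CF1", "CDF1", "CF2", "CDF2", "CF3"]
    for j, code in enumerate(codes):
        for r in range(1, n_replicates + 1):
            row = chr(ord("A") + r - 1)
            wells[f"{row}{j + 1}"] = WellCondition(
                condition_code=code, patient_id=patient_id, replicate=r
            )
    return PlateLayout(wells)


def generate_cohort_profiles(
    n: int,
    seed: int | None = None,
    mixture: MixtureSpec = DEFAULT_COHORT_MIXTURE,
    n_combined_positive: int | None = None,
    cutoff: float = 250.0,
    noise_sd: float = 0.05,
) -> list[PatientProfile]:
    """Build per-patient profiles whose scored plates reproduce the cohort.

    Capacities are chosen so that the *observed* score (capacity times the
    0.9 standard-dose occupancy) follows the mixture.  When
    ``n_combined_positive`` is given, exactly that many patients are planted
    as combined positives (c-Met score above the cutoff and one HER pathway
    above it, with a safety margin of 1.4x cutoff / 0.6x cutoff against
    noise); the rest are all-pathway negative.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    occ = median_effect_fa(
        DEFAULT_AGONIST_DOSE_M["HGF"], *DEFAULT_AGONIST_POTENCY["HGF"]
    )

    def draw_score(lo: float | None = None, hi: float | None = None) -> float:
        for _ in range(10_000):
            k = rng.choice(mixture.k, p=mixture.weights)
            s = rng.normal(mixture.means[k], mixture.sds[k])
            if (lo is None or s >= lo) and (hi is None or s <= hi):
                return float(s)
        raise ValidationError("truncated mixture draw failed")

    if n_combined_positive is not None and not (0 <= n_combined_positive <= n):
        raise ValidationError("n_combined_positive must be in [0, n]")
    profiles = []
    her = ("HER1", "HER2", "HER3_4")
    for i in range(n):
        pid = f"P{i + 1:04d}"
        cap: dict[str, float] = {}
        if n_combined_positive is None:
            cap["cMet"] = draw_score() / occ
            for p in her:
                cap[p] = max(0.0, rng.normal(120.0, 80.0)) / occ
        elif i < n_combined_positive:
            cap["cMet"] = draw_score(lo=1.4 * cutoff) / occ
            hot = her[int(rng.integers(len(her)))]
            for p in her:
                cap[p] = (draw_score(lo=1.4 * cutoff) if p == hot
                          else draw_score(hi=0.6 * cutoff, lo=0.0)) / occ
        else:
            cap["cMet"] = draw_score(hi=0.6 * cutoff, lo=0.0) / occ
            for p in her:
                cap[p] = draw_score(hi=0.6 * cutoff, lo=0.0) / occ
        profiles.append(PatientProfile(pid, cap, noise_sd=noise_sd))
    return profiles


# ---------------------------------------------------------------------------
# combination surfaces
# ---------------------------------------------------------------------------

def _dx(fa: float, dm: float, m: float) -> float:
    return dm * (fa / (1.0 - fa)) ** (1.0 / m)


def solve_surface_fa(
    d1: float, d2: float, drug1: DrugSpec, drug2: DrugSpec, alpha: float
) -> float:
    """Self-consistent fraction affected of a two-drug exposure.

    Solves ``d1/Dx1(fa) + d2/Dx2(fa) + alpha (d1/Dm1)(d2/Dm2) = 1``.
    With ``alpha = 0`` this is exactly Loewe additivity.  If the
    interaction term alone exceeds 1 the effect saturates and fa is clamped
    just below 1.
    """
    if alpha < -1:
        raise ValidationError("alpha must be >= -1")
    cross = alpha * (d1 / drug1.dm_molar) * (d2 / drug2.dm_molar)

    def g(fa: float) -> float:
        tot = cross - 1.0
        if d1 > 0:
            tot += d1 / _dx(fa, drug1.dm_molar, drug1.m)
        if d2 > 0:
            tot += d2 / _dx(fa, drug2.dm_molar, drug2.m)
        return tot

    lo, hi = 1e-12, 1.0 - 1e-12
    if g(hi) > 0:        # even near-total effect cannot satisfy the balance
        return hi
    if g(lo) < 0:
        return lo
    return float(brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200))


def generate_combination_surface(
    drug1: DrugSpec,
    drug2: DrugSpec,
    alpha: float,
    dose_grid: Sequence[tuple[float, float]],
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Fraction-affected table over a grid of dose pairs.

    ``alpha = 0`` yields an exactly Loewe-additive surface; positive alpha
    synergy, negative alpha antagonism.  Optional Gaussian noise on fa is
    clipped to (0, 1).
    """
    pairs = [(float(a), float(b)) for a, b in dose_grid]
    if any(a <= 0 or b <= 0 for a, b in pairs):
        raise ValidationError("dose grid must be strictly positive")
    rng = np.random.default_rng(seed)
    rows = []
    for d1, d2 in pairs:
        fa = solve_surface_fa(d1, d2, drug1, drug2, alpha)
        if noise_sd > 0:
            fa = float(np.clip(fa + rng.normal(0.0, noise_sd), 1e-6, 1 - 1e-6))
        rows.append({"dose1_molar": d1, "dose2_molar": d2, "fa": fa})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# xenograft volumes
# ---------------------------------------------------------------------------

def generate_xenograft(
    arms: Sequence[Mapping],
    g: float = 0.08,
    v0: float = 150.0,
    days: int = 21,
    noise_cv: float = 0.25,
    seed: int | None = None,
    measure_every: int = 3,
) -> pd.DataFrame:
    """Simulate tumor volume trajectories per arm.

    Each arm is ``{"name": str, "n_mice": int >= 2, "effect": e in [0, 1]}``;
    volumes follow ``V0 exp(g (1 - e) t)`` with mean-preserving lognormal
    measurement noise of coefficient of variation ``noise_cv``.
    """
    if days < 1:
        raise ValidationError("days must be >= 1")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    day_grid = sorted(set(range(0, days, measure_every)) | {days})
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for arm in arms:
        name, n_mice, e = arm["name"], int(arm["n_mice"]), float(arm["effect"])
        if n_mice < 2:
            raise ValidationError(f"arm {name}: n_mice must be >= 2")
        if not (0.0 <= e <= 1.0):
            raise ValidationError(f"arm {name}: effect must be in [0, 1]")
        for mouse in range(1, n_mice + 1):
            mouse_id = f"{name}-{mouse:02d}"
            for day in day_grid:
                mean_v = v0 * np.exp(g * (1.0 - e) * day)
                noise = np.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma > 0 else 1.0
                rows.append({
                    "mouse_id": mouse_id, "arm": name,
                    "day": float(day), "volume_mm3": mean_v * noise,
                })
    return pd.DataFrame(rows)
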
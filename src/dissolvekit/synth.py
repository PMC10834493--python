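"""Synthetic dissolution studies with realistic immediate-release structure.

The generator draws replicate percent-released profiles from a Weibull
release curve with an optional post-peak linear decline,

    m(t) = f_inf * (1 - exp(-(t/tau)^beta)) - decay * max(0, t - t_peak)

where t_peak is the first grid time at which the pure Weibull part
reaches 95 % of its asymptote.  beta = 1 recovers first-order release.
The decline term mimics the slight late decrease real cumulative
profiles of fast-dissolving tablets can show (degradation, adsorption,
or accumulated sampling error), so that generated references are not
artificially monotone.  Replicate noise is independent Gaussian per
time point, truncated at zero; the SD may be a per-time vector to copy
a heteroscedastic pattern.

This is a data *emulator* for pipeline testing, not a kinetic model to
be fitted to real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import GenerationError
from .profiles import DissolutionProfile, Study, TimeGrid
from .quant import AreaTable, QuantConfig, standard_concentration, vessel_volumes


@dataclass(frozen=True)
class ReleaseModelParams:
    """Parameters of the Weibull-with-decline release model.

    f_inf : asymptotic percent released, in (0, 110].
    tau : time scale in minutes.
    beta : Weibull shape exponent; 1 = first-order.
    decay : post-peak linear decline, % per minute, >= 0.
    noise_sd : replicate SD in % units, scalar or one value per grid time.
    n_reps : replicate vessels per profile.
    """

    f_inf: float = 99.0
    tau: float = 3.0
    beta: float = 1.0
    decay: float = 0.0
    noise_sd: float | tuple[float, ...] = 1.0
    n_reps: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.f_inf <= 110:
            raise ValueError("f_inf must be in (0, 110]")
        if self.tau <= 0 or self.beta <= 0:
            raise ValueError("tau and beta must be > 0")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if np.any(sd < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if isinstance(self.noise_sd, (list, np.ndarray)):
            object.__setattr__(self, "noise_sd", tuple(float(x) for x in sd))


def mean_curve(params: ReleaseModelParams, grid: TimeGrid) -> np.ndarray:
    """Noise-free mean percent released at each grid time."""
    t = grid.as_array()
    m = params.f_inf * (1.0 - np.exp(-((t / params.tau) ** params.beta)))
    if params.decay > 0:
        at_peak = m >= 0.95 * params.f_inf
        if at_peak.any():
            t_peak = t[np.argmax(at_peak)]
            m = m - params.decay * np.maximum(0.0, t - t_peak)
    return np.clip(m, 0.0, None)


def _noise_vector(params: ReleaseModelParams, n_times: int) -> np.ndarray:
    sd = np.atleast_1d(np.asarray(params.noise_sd, dtype=float))
    if sd.size == 1:
        return np.full(n_times, sd[0])
    if sd.size != n_times:
        raise ValueError(
            f"noise_sd has {sd.size} entries for {n_times} grid times"
        )
    return sd


def generate_profile(
    params: ReleaseModelParams,
    grid: TimeGrid,
    label: str,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> DissolutionProfile:
    """Draw one replicate profile; deterministic for a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = mean_curve(params, grid)
    sd = _noise_vector(params, len(grid))
    reps = m[:, None] + rng.standard_normal((len(grid), params.n_reps)) * sd[:, None]
    reps = np.clip(reps, 0.0, None)
    return DissolutionProfile(product_label=label, grid=grid, replicates=reps)


@dataclass(frozen=True)
class StudyPreset:
    """A named generator configuration: grid, reference parameters, and
    per-test parameter offsets."""

    name: str
    grid: TimeGrid
    reference: ReleaseModelParams
    test_deltas: tuple[Mapping[str, float], ...]
    reference_label: str = "Ref"
    method: Mapping[str, object] = field(default_factory=dict)


def _perturb(base: ReleaseModelParams, delta: Mapping[str, float]) -> ReleaseModelParams:
    """Additive offsets on f_inf/tau/beta/decay; other fields replace."""
    kwargs: dict[str, object] = {}
    for key, val in delta.items():
        if key == "label":
            continue
        if key in ("f_inf", "tau", "beta", "decay"):
            kwargs[key] = getattr(base, key) + float(val)
        elif key in ("noise_sd", "n_reps"):
            kwargs[key] = val
        else:
            raise ValueError(f"unknown parameter {key!r} in perturbation")
    return replace(base, **kwargs)


def generate_study(
    ref_params: ReleaseModelParams,
    test_deltas: Sequence[Mapping[str, float]],
    grid: TimeGrid,
    seed: int,
    reference_label: str = "Ref",
    method: Mapping[str, object] | None = None,
) -> Study:
    """Reference plus perturbed test profiles, all driven by one seed.

    Each profile gets an independent child stream of the seed, so adding
    a test never changes the reference draw.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + len(test_deltas))
    ref = generate_profile(ref_params, grid, reference_label, np.random.default_rng(children[0]))
    tests = []
    for k, delta in enumerate(test_deltas):
        label = str(delta.get("label", f"T-{k + 1}"))
        p = _perturb(ref_params, delta)
        tests.append(generate_profile(p, grid, label, np.random.default_rng(children[k + 1])))
    return Study(reference=ref, tests=tests, method=dict(method or {}))


def generate_from_preset(preset: StudyPreset, seed: int) -> Study:
    return generate_study(
        preset.reference, preset.test_deltas, preset.grid, seed,
        reference_label=preset.reference_label, method=preset.method,
    )


def load_preset(name_or_path: str) -> StudyPreset:
    """Load a preset by packaged name (e.g. ``vildagliptin_mimic``) or
    from a YAML file path."""
    from pathlib import Path

    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
        name = p.stem
    else:
        res = resources.files("dissolvekit.data") / f"{name_or_path}.yaml"
        if not res.is_file():
            available = sorted(
                f.name[:-5]
                for f in resources.files("dissolvekit.data").iterdir()
                if f.name.endswith(".yaml") and f.name != "method_default.yaml"
            )
            raise GenerationError(
                f"unknown preset {name_or_path!r}; available: "
                + ", ".join(available)
            )
        text = res.read_text()
        name = name_or_path
    doc = yaml.safe_load(text)
    ref = ReleaseModelParams(**doc["reference"])
    return StudyPreset(
        name=name,
        grid=TimeGrid(doc["grid"]),
        reference=ref,
        test_deltas=tuple(doc.get("test_deltas", [])),
        reference_label=doc.get("reference_label", "Ref"),
        method=doc.get("method", {}),
    )


# ---------------------------------------------------------------------------
# inverse quantitation: profiles -> peak areas
# ---------------------------------------------------------------------------

def generate_area_table(
    profile: DissolutionProfile,
    cfg: QuantConfig,
    std_area: float = 1.0e6,
) -> AreaTable:
    """Peak areas whose forward quantitation reproduces ``profile``.

    Inverts the cumulative aliquot-withdrawal correction sampling time
    by sampling time: given cumulative percents p_i, the concentration
    at time i is

        C_i = (p_i * label/100 - w * sum_{j<i} C_j) / V_i

    and areas follow from the external-standard ratio.  A profile whose
    percents decrease faster than withdrawal can explain implies a
    non-positive concentration and is rejected.
    """
    if profile.summary_only:
        raise GenerationError("area generation needs replicate profiles")
    pct = profile.replicates
    n_t = pct.shape[0]
    v = vessel_volumes(cfg, n_t)
    conc = np.empty_like(pct)
    prior = np.zeros(pct.shape[1])
    for i in range(n_t):
        mass = pct[i] * cfg.label_claim_mg / 100.0
        conc[i] = (mass - cfg.withdrawal_vol_ml * prior) / v[i]
        if np.any(conc[i] <= 0):
            raise GenerationError(
                f"profile implies non-positive concentration at time index {i}"
            )
        prior = prior + conc[i]
    areas = conc / standard_concentration(cfg) * std_area
    return AreaTable(grid=profile.grid, sample_areas=areas, std_area=std_area)
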
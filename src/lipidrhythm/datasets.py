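"""Synthetic serum-lipidomics datasets with the hierarchy's exact structure.

The generator emulates a two-group circadian sampling study: two groups of
subjects (healthy controls and RA patients) sampled a handful of times
over 24 h (default: five samples at 6-hourly intervals starting 18:00),
with ~116 analytes spanning ceramide, eicosanoid and endocannabinoid
classes.  Each rhythmic analyte carries a shared 24 h component common to
all subjects of a group; every subject adds an independent smooth Matern
3/2 deviation; i.i.d. Gaussian noise and sporadic missing values complete
the observation model.

Two rhythmic-signal modes are provided:

* ``"cosinor"`` (default): g(t) = amplitude * sqrt(2) * cos(2 pi (t - acrophase)/24),
  a deterministic cosine whose temporal SD equals ``amplitude`` — the mode
  used for acrophase-recovery tests, where the injected truth must be known;
* ``"gp"``: g drawn once per (analyte, group) from the periodic-kernel GP,
  matching the probabilistic model exactly (random phase and shape).

Ground truth (rhythmic flag, acrophase, amplitude per analyte/group) is
returned as side-channel metadata, never as columns of the measurement
table, so pipeline code cannot peek.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .kernels import KernelParams, add_jitter, matern32_kernel, periodic_kernel

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "make_null_dataset",
    "build_analyte_names",
]

GROUPS = ("healthy", "RA")

_EICOSANOIDS = [
    "9-HODE", "13-HODE", "9HOTrE", "13HOTrE", "12(13)EpOME", "9(10)EpOME",
    "5-HETE", "8-HETE", "11-HETE", "12-HETE", "15-HETE", "20-HETE",
    "PGE2", "PGD2", "PGF2a", "TXB2", "LTB4", "14,15-DHET",
    "AEA", "2-AG", "PEA", "OEA", "LEA", "DHEA",
]


def build_analyte_names(n: int) -> list[str]:
    """Deterministic roster of ``n`` analyte labels.

    Ceramides (valid ``CER[X(a)Y(b)]`` nomenclature over the four
    structural classes) come first, padded with eicosanoid/endocannabinoid
    names; the default study size of 116 is covered without repeats.
    """
    ceramides = [
        f"CER[{fa}({fa_c}){base}({base_c})]"
        for fa in ("N", "A")
        for base in ("DS", "S")
        for fa_c in (16, 18, 20, 22, 24, 26)
        for base_c in (16, 18, 20, 24)
    ]
    names = ceramides[: max(0, n - len(_EICOSANOIDS))] + _EICOSANOIDS
    if n > len(names):
        names += [f"LIPID-{i:03d}" for i in range(n - len(names))]
    return names[:n]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generative parameters of a synthetic dataset.

    Defaults mirror the clinical design: 10 subjects per group, five
    samples at 6-hourly intervals from 18:00, 116 lipid analytes, unit
    noise on the normalised scale, subject-deviation SD 0.5, and sporadic
    (1%) missingness.
    """

    n_subjects_per_group: int = 10
    sample_times: tuple = (18.0, 6.0, 5)  # (start_hour, interval_h, n) or explicit times
    n_analytes: int = 116
    fraction_rhythmic_per_group: tuple = (0.2, 0.4)
    amplitude: float = 1.0
    acrophases: object = "random"  # "random", scalar hour, or sequence per analyte
    subject_dev_sd: float = 0.5
    subject_dev_lengthscale: float = 12.0
    noise_sd: float = 1.0
    missing_rate: float = 0.01
    seed: int = 0
    signal_mode: str = "cosinor"  # "cosinor" | "gp"
    groups: tuple = GROUPS
    rhythmic_assignment: dict | None = None  # optional {group: set of analyte indices}

    def resolved_sample_times(self) -> np.ndarray:
        st = self.sample_times
        # a (start, interval, n) triple is recognised by an *integer* count;
        # three explicit clock times should be given as floats
        if len(st) == 3 and isinstance(st[2], (int, np.integer)) and st[2] >= 2:
            start, interval, n = float(st[0]), float(st[1]), int(st[2])
            times = start + interval * np.arange(n)
        else:
            times = np.asarray(st, dtype=float)
        return times

    def validate(self) -> "SimulationConfig":
        if self.n_subjects_per_group < 1:
            raise ValueError(f"n_subjects_per_group must be >= 1, got {self.n_subjects_per_group}")
        if self.n_analytes < 1:
            raise ValueError(f"n_analytes must be >= 1, got {self.n_analytes}")
        times = self.resolved_sample_times()
        if np.any(times < 0) or np.any(times >= 48):
            raise ValueError(f"sample_times must lie in [0, 48) after unwrapping, got {times}")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"sample_times must be strictly increasing, got {times}")
        for g, frac in zip(self.groups, self.fraction_rhythmic_per_group):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction_rhythmic_per_group[{g}] must be in [0,1], got {frac}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.subject_dev_sd < 0:
            raise ValueError(f"subject_dev_sd must be >= 0, got {self.subject_dev_sd}")
        if self.subject_dev_lengthscale <= 0:
            raise ValueError(
                f"subject_dev_lengthscale must be > 0, got {self.subject_dev_lengthscale}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.signal_mode not in ("cosinor", "gp"):
            raise ValueError(f"signal_mode must be 'cosinor' or 'gp', got {self.signal_mode!r}")
        return self

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        if d.get("rhythmic_assignment") is not None:
            d["rhythmic_assignment"] = {g: sorted(s) for g, s in d["rhythmic_assignment"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("sample_times", "fraction_rhythmic_per_group", "groups", "acrophases"):
            if isinstance(d.get(k), list):
                d[k] = tuple(d[k])
        if d.get("rhythmic_assignment") is not None:
            d["rhythmic_assignment"] = {g: set(v) for g, v in d["rhythmic_assignment"].items()}
        return cls(**d)


@dataclass
class SyntheticDataset:
    """A simulated long table plus its side-channel ground truth."""

    table: pd.DataFrame
    truth: pd.DataFrame  # per (analyte, group): rhythmic, acrophase_h, amplitude
    config: SimulationConfig = field(repr=False, default=None)

    def write(self, table_path, truth_path=None) -> None:
        self.table.to_csv(table_path, index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


def _rhythmic_indices(config: SimulationConfig) -> dict:
    if config.rhythmic_assignment is not None:
        return {g: set(config.rhythmic_assignment.get(g, ())) for g in config.groups}
    out = {}
    for gi, (g, frac) in enumerate(zip(config.groups, config.fraction_rhythmic_per_group)):
        n_rhythmic = int(round(frac * config.n_analytes))
        rng = np.random.default_rng([config.seed, 1_000_000 + gi])
        out[g] = set(rng.choice(config.n_analytes, size=n_rhythmic, replace=False).tolist())
    return out


def _acrophases(config: SimulationConfig) -> np.ndarray:
    if isinstance(config.acrophases, str):
        if config.acrophases != "random":
            raise ValueError(f"acrophases must be 'random', a number or a sequence")
        rng = np.random.default_rng([config.seed, 2_000_000])
        return rng.uniform(0.0, 24.0, size=config.n_analytes)
    arr = np.atleast_1d(np.asarray(config.acrophases, dtype=float))
    if arr.size == 1:
        arr = np.full(config.n_analytes, float(arr[0]))
    if arr.size != config.n_analytes:
        raise ValueError("acrophases sequence length must equal n_analytes")
    if np.any((arr < 0) | (arr >= 24)):
        raise ValueError("acrophases must lie in [0, 24)")
    return arr


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Sample one dataset from the hierarchical generative model.

    For each rhythmic (analyte, group) the shared component g is either a
    deterministic cosine at the configured acrophase (``cosinor`` mode) or
    one draw from the 24 h periodic-kernel GP (``gp`` mode).  Each subject
    adds an independent Matern 3/2 draw; i.i.d. noise and Bernoulli
    missingness complete the table.  Bit-identical under the same seed;
    per-analyte random substreams are derived from (seed, analyte index).
    """
    config.validate()
    times = config.resolved_sample_times()
    names = build_analyte_names(config.n_analytes)
    rhythmic = _rhythmic_indices(config)
    acro = _acrophases(config)

    # covariance factors over the per-subject time grid, computed once
    kp = KernelParams(
        sigma2_p=config.amplitude**2 or 1.0, ell_p=1.0,
        sigma2_m=config.subject_dev_sd**2 or 1.0, ell_m=config.subject_dev_lengthscale,
        sigma2_n=config.noise_sd**2,
    )
    L_per = np.linalg.cholesky(add_jitter(periodic_kernel(times, times, kp))) \
        if config.amplitude > 0 else None
    L_mat = np.linalg.cholesky(add_jitter(matern32_kernel(times, times, kp))) \
        if config.subject_dev_sd > 0 else None

    subjects = {
        g: [f"{'H' if g == 'healthy' else g.upper()}{i + 1:02d}"
            for i in range(config.n_subjects_per_group)]
        for g in config.groups
    }

    rows = []
    truth_rows = []
    for k, name in enumerate(names):
        rng = np.random.default_rng([config.seed, k])
        for g in config.groups:
            is_rhythmic = k in rhythmic[g]
            if is_rhythmic:
                if config.signal_mode == "cosinor":
                    shared = config.amplitude * np.sqrt(2.0) * np.cos(
                        2.0 * np.pi * (times - acro[k]) / 24.0
                    )
                elif L_per is not None:
                    shared = L_per @ rng.standard_normal(times.size)
                else:  # gp mode with zero amplitude: no signal
                    shared = np.zeros(times.size)
            else:
                shared = np.zeros(times.size)
                # keep the substream aligned across rhythmic/null configs
                if config.signal_mode == "gp":
                    rng.standard_normal(times.size)
            for si, subject in enumerate(subjects[g]):
                dev = (L_mat @ rng.standard_normal(times.size)
                       if L_mat is not None else np.zeros(times.size))
                noise = config.noise_sd * rng.standard_normal(times.size)
                values = shared + dev + noise
                miss = rng.random(times.size) < config.missing_rate
                for ti, t in enumerate(times):
                    rows.append((
                        subject, g, float(t), name,
                        np.nan if miss[ti] else float(values[ti]),
                    ))
            truth_rows.append({
                "analyte": name, "group": g, "rhythmic": is_rhythmic,
                "acrophase_h": float(acro[k]) if (is_rhythmic and config.signal_mode == "cosinor")
                else np.nan,
                "amplitude": config.amplitude if is_rhythmic else 0.0,
            })

    table = pd.DataFrame(rows, columns=["subject", "group", "time_h", "analyte", "value"])
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(table=table, truth=truth, config=config)


def make_null_dataset(config: SimulationConfig) -> SyntheticDataset:
    """As :func:`simulate_dataset` with no rhythmic analytes in either group.

    Subject deviations and noise are retained; used for test-size
    calibration of the rhythmicity test.
    """
    null_cfg = replace(
        config,
        fraction_rhythmic_per_group=tuple(0.0 for _ in config.groups),
        rhythmic_assignment=None,
    )
    return simulate_dataset(null_cfg)
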
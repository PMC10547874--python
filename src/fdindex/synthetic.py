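"""Synthetic source spaces, current matrices and cohorts with known structure.

The study data (clinical resting-state EEG source currents) are not
publicly deposited, so every downstream stage is exercised on simulated
inputs whose statistical structure is controlled:

* sources live on a sphere surface (cortex-like sheet) so instantaneous
  activation clouds are quasi-2-D, the geometric regime of real source
  models;
* each network's sources share a fractional-Brownian-motion envelope whose
  Hurst exponent sets the temporal roughness — and therefore the
  complexity — of the activation dynamics; the patient group's Hurst
  exponent is shifted by a configurable amount;
* synthetic positive-symptom scores are generated with a negative monotone
  link to each subject's complexity so correlation recovery is testable.

Analytic fixtures with known fractal dimension (Cantor dusts, fBm with
Higuchi dimension 2 - H) provide exact oracles for the estimators.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import NETWORKS, NO_NETWORK, CohortTable, CurrentMatrix, SourceSpace

__all__ = [
    "SimulationConfig",
    "make_source_space",
    "make_fbm",
    "make_current_matrix",
    "make_cantor_dust",
    "make_cohort",
]

#: Default network shares: five equal patches covering 75% of the sphere.
DEFAULT_NETWORKS = tuple((label, 0.15) for label in NETWORKS)

#: Between-subject SD of the envelope Hurst exponent within a group; large
#: enough that subject-level complexity differences dominate the windowing
#: noise of a short record, small against typical group effects (~0.4).
_HURST_JITTER_SD = 0.08


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    ``hurst`` is the Hurst exponent of the shared network envelopes for
    healthy subjects; ``group_effect`` is added for patients (a positive
    shift smooths the dynamics and lowers the complexity index).
    ``activation_extent`` is the fraction of each network's sources that
    share the envelope and can activate; the rest stay silent.
    ``noise_sd`` is the spread of the per-source Gaussian offsets that
    stagger the activation levels of the shared sources.
    """

    n_sources: int = 2000
    networks: tuple[tuple[str, float], ...] = DEFAULT_NETWORKS
    fs: float = 250.0
    duration: float = 30.0
    hurst: float = 0.5
    activation_extent: float = 0.8
    noise_sd: float = 0.3
    group_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.networks)
        if total > 1 + 1e-12:
            raise ValueError(f"network fractions sum to {total} > 1")
        for h in (self.hurst, self.hurst + self.group_effect):
            if not 0 < h < 1:
                raise ValueError(f"hurst exponent {h} outside (0, 1)")
        if not 0 < self.activation_extent <= 1:
            raise ValueError("activation_extent must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs)


def make_source_space(
    n_sources: int,
    networks: tuple[tuple[str, float], ...] = DEFAULT_NETWORKS,
    seed: int = 0,
    radius: float = 70.0,
) -> SourceSpace:
    """Sources on a sphere surface with contiguous angular network patches.

    Positions are sampled uniformly on a sphere of the given radius (mm,
    roughly head-sized) and sorted by azimuth; each network then occupies a
    contiguous longitude wedge whose share of the sources equals its
    fraction.  Leftover sources are labelled ``NONE``.
    """
    if n_sources < len(networks):
        raise ValueError("need at least one source per network")
    total = sum(f for _, f in networks)
    if total > 1 + 1e-12:
        raise ValueError(f"network fractions sum to {total} > 1")
    rng = np.random.default_rng(seed)
    xyz = rng.standard_normal((n_sources, 3))
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    xyz *= radius
    order = np.argsort(np.arctan2(xyz[:, 1], xyz[:, 0]), kind="stable")
    xyz = xyz[order]
    labels = np.full(n_sources, NO_NETWORK, dtype=object)
    start = 0
    for label, frac in networks:
        count = round(frac * n_sources)
        labels[start : start + count] = label
        start += count
    return SourceSpace(positions=xyz, networks=labels)


def _fgn_davies_harte(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise by circulant embedding of the fGn covariance.

    The circulant eigenvalues are theoretically nonnegative for fGn; tiny
    negative values from floating-point round-off are clipped to zero and
    the spectrum renormalised, which degrades the covariance only at the
    round-off level.
    """
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    eig = np.fft.rfft(row).real
    neg = eig < 0
    if neg.any():
        eig = np.where(neg, 0.0, eig)
        eig *= row[0] * 2 * n / eig.sum() if eig.sum() > 0 else 1.0
    m = 2 * n
    # Hermitian-symmetric Gaussian spectrum -> real stationary series
    z = rng.standard_normal(m)
    spec = np.fft.rfft(z) * np.sqrt(eig / m)
    return np.fft.irfft(spec, n=m)[:n]


def make_fbm(n: int, hurst: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Fractional Brownian motion of length ``n`` with Hurst exponent ``hurst``.

    Synthesised as the cumulative sum of exact-covariance fractional
    Gaussian noise (Davies-Harte circulant embedding).  The Higuchi
    dimension of the result is ``2 - hurst``, which makes these traces the
    oracle for the Higuchi estimator.
    """
    if n < 64:
        raise ValueError("n must be >= 64")
    if not 0 < hurst < 1:
        raise ValueError(f"hurst exponent {hurst} outside (0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return np.cumsum(_fgn_davies_harte(n, hurst, rng))


def make_current_matrix(
    space: SourceSpace,
    config: SimulationConfig,
    subject_id: str = "S000",
    hurst: float | None = None,
    seed: int | None = None,
) -> CurrentMatrix:
    """Simulated source currents for one subject.

    Per network (the unassigned remainder counts as its own group, so the
    whole-brain analysis sees structure too), the first
    ``activation_extent`` share of its sources carries a common
    standardised fBm envelope, each source shifted by an independent
    Gaussian offset of SD ``noise_sd``.  The offsets stagger the levels at
    which sources cross their activation thresholds, so the instantaneous
    cloud waxes and wanes gradually with the envelope and the 3DFD time
    course inherits the envelope's roughness (a step the all-or-nothing
    limit ``noise_sd = 0`` collapses: there every shared source of a
    network carries an identical series and activates in lockstep).
    Sources outside the shared fraction stay silent.
    """
    t = config.n_samples
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h = config.hurst if hurst is None else hurst
    if not 0 < h < 1:
        raise ValueError(f"hurst exponent {h} outside (0, 1)")
    values = np.zeros((space.n_sources, t))
    for label in list(dict.fromkeys(space.networks)):
        rows = np.flatnonzero(space.networks == label)
        envelope = make_fbm(t, h, rng)
        envelope = (envelope - envelope.mean()) / envelope.std()
        n_shared = int(np.ceil(config.activation_extent * len(rows)))
        offsets = rng.normal(0.0, config.noise_sd, n_shared) if config.noise_sd else np.zeros(n_shared)
        values[rows[:n_shared], :] = envelope[None, :] + offsets[:, None]
    return CurrentMatrix(subject_id=subject_id, values=values, fs=config.fs)


def make_cantor_dust(dim: int, levels: int, base: int = 3) -> np.ndarray:
    """Cartesian product of middle-thirds Cantor prefractals.

    Returns a dense boolean grid of side ``base**levels`` in ``dim``
    dimensions with ``2**(dim*levels)`` occupied cells.  Its box-counting
    dimension over scales ``{1, base, base**2, ...}`` is exactly
    ``dim * ln 2 / ln base``.
    """
    if dim not in (1, 2, 3, 4):
        raise ValueError("dim must be in {1, 2, 3, 4}")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if base < 3:
        raise ValueError("base must be >= 3")
    side = base**levels
    if side**dim > 10**8:
        raise ValueError(f"grid of {side}^{dim} cells exceeds the safety limit")
    keep = np.ones(1, dtype=bool)
    for _ in range(levels):
        block = np.zeros(base, dtype=bool)
        block[0] = block[-1] = True  # keep the two outer thirds
        keep = np.kron(keep, block)
    grid = keep
    for _ in range(dim - 1):
        grid = np.multiply.outer(grid, keep)
    return grid


def _sample_covariates(
    group: str, rng: np.random.Generator
) -> dict[str, float | str]:
    """Demographics and cognitive scores matching the study's group profiles."""
    if group == "SCZ":
        age_mu, age_sd = 36.2, 10.2
        p_male = 9 / 11
        edu_p = np.array([2, 8, 1], dtype=float)
        scip = {"VLi": (16.2, 3.9), "VLd": (5.8, 2.1), "VF": (13.6, 4.5),
                "WM": (16.7, 4.0), "PS": (7.6, 3.0)}
    else:
        age_mu, age_sd = 40.7, 11.9
        p_male = 13 / 20
        edu_p = np.array([1, 12, 7], dtype=float)
        scip = {"VLi": (21.1, 4.4), "VLd": (6.8, 2.4), "VF": (17.9, 4.1),
                "WM": (19.5, 3.0), "PS": (11.3, 2.9)}
    edu_p /= edu_p.sum()
    row: dict[str, float | str] = {
        "age": float(np.clip(rng.normal(age_mu, age_sd), 18, 80)),
        "sex": "M" if rng.random() < p_male else "F",
        "education": rng.choice(["Primary", "Secondary", "High"], p=edu_p),
    }
    for name, (mu, sd) in scip.items():
        row[name] = float(np.clip(rng.normal(mu, sd), 0, 30))
    return row


def make_cohort(
    n_hc: int,
    n_scz: int,
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[SourceSpace, list[CurrentMatrix], CohortTable]:
    """Simulated cohort: shared source space, per-subject currents, table.

    Each subject's envelope Hurst exponent is the group value
    (``config.hurst``, shifted by ``config.group_effect`` for patients)
    plus a small individual jitter.  Synthetic PANSS scores for patients
    decrease with the subject's complexity (i.e. increase with the Hurst
    exponent), so a negative FDI-PANSS correlation is built in and
    recoverable.  PANSS columns are absent (NaN) for controls.
    """
    if n_hc < 2 or n_scz < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    space = make_source_space(config.n_sources, config.networks, seed=seed)
    matrices: list[CurrentMatrix] = []
    rows = []
    space_groups = [("HC", n_hc), ("SCZ", n_scz)]
    idx = 0
    for group, count in space_groups:
        for _ in range(count):
            sid = f"{group}{idx:03d}"
            base_h = config.hurst + (config.group_effect if group == "SCZ" else 0.0)
            h = float(np.clip(base_h + rng.normal(0, _HURST_JITTER_SD), 0.05, 0.95))
            row: dict[str, float | str] = {"subject_id": sid, "group": group}
            row.update(_sample_covariates(group, rng))
            if group == "SCZ":
                # severity rises as dynamics smooth out (complexity falls)
                z = (h - base_h) / _HURST_JITTER_SD + rng.normal(0, 0.3)
                row["PANSS_P"] = float(np.clip(13.9 + 4.5 * z, 7, 49))
                row["PANSS_N"] = float(np.clip(19.3 + 8.2 * (0.6 * z + rng.normal(0, 0.8)), 7, 49))
                row["PANSS_G"] = float(np.clip(29.4 + 7.1 * (0.6 * z + rng.normal(0, 0.8)), 16, 112))
            else:
                row["PANSS_P"] = np.nan
                row["PANSS_N"] = np.nan
                row["PANSS_G"] = np.nan
            rows.append(row)
            idx += 1
            matrices.append(
                make_current_matrix(
                    space,
                    config,
                    subject_id=sid,
                    hurst=h,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
    return space, matrices, CohortTable(pd.DataFrame(rows))
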
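"""Synthetic two-group expression data with known planted structure.

The generator emulates the statistical shape of a normalized bulk
transcriptomic study contrasting two groups of women (42 nulliparous
reference samples vs 71 parous contrast samples by default): Gaussian
background expression on a log-like scale, plus optional planted blocks that
exercise every downstream analysis stage:

* ``mean_shift``       -- probes whose contrast-group mean moves by a stated
                          number of baseline SDs (up or down),
* ``shape_shift``      -- equal-mean probes whose contrast-group variance is
                          inflated, changing the distribution but not the mean,
* ``entropy_shift``    -- equal-mean probes whose contrast-group values spread
                          uniformly over a wide range, raising discretized
                          Shannon entropy,
* ``modules``          -- groups of probes sharing a latent factor, with a
                          configurable within-module correlation per group,
* ``quadruplets``      -- 4-probe linear relations whose fit quality (R^2)
                          differs between groups.

Each block draws from an independent, seeded random stream, so adding or
resizing one block never perturbs the values generated for the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CONTRAST_GROUP, REFERENCE_GROUP, ExpressionDataset


class ConfigurationError(ValueError):
    """Raised for an inconsistent synthetic-data configuration."""


# --------------------------------------------------------------------------
# configuration blocks
# --------------------------------------------------------------------------


@dataclass
class MeanShiftBlock:
    """Probes with a pure location shift in the contrast group.

    ``effect_size`` is in units of the baseline SD.  ``fraction_up`` sets the
    share of shifted probes that move upward; the default reflects the roughly
    2.2:1 up/down-regulation ratio typical of the parity contrast.
    """

    count: int = 0
    effect_size: float = 1.0
    fraction_up: float = 0.685


@dataclass
class ShapeShiftBlock:
    """Equal-mean probes whose contrast-group variance is multiplied.

    The default triples the SD (variance x9), a distributional change large
    enough for rank/KS tests to see reliably at n ~ 40-70 while the mean
    criterion stays blind to it."""

    count: int = 0
    variance_ratio: float = 9.0


@dataclass
class EntropyShiftBlock:
    """Equal-mean probes drawn uniformly over a widened range in the
    contrast group, so discretized entropy rises while the mean does not.
    ``dispersion_ratio`` is the SD inflation of the uniform relative to the
    Gaussian baseline."""

    count: int = 0
    dispersion_ratio: float = 3.0


@dataclass
class ModuleBlock:
    """Correlated probe modules via a shared latent factor per module/group.

    A loading ``a`` with unit idiosyncratic noise gives pairwise correlation
    ``rho = a^2 / (a^2 + 1)``; the loading is solved from the configured
    ``rho`` per group.  The default plants modules correlated only in the
    contrast group (rho 0.9 vs 0.0)."""

    n_modules: int = 0
    module_size: int = 10
    within_correlation_group1: float = 0.0
    within_correlation_group2: float = 0.9

    @property
    def count(self) -> int:
        return self.n_modules * self.module_size


@dataclass
class QuadrupletBlock:
    """Planted 4-probe linear relations probe1 ~ probe2 + probe3 + probe4.

    The lead regressor is up-weighted (``lead_weight``) so that the
    (probe1, probe2) seed pair is strongly correlated in the low-noise group,
    as required for it to surface in the correlation-based seed-pair classes
    of the regression screen.  Per-group noise SDs set the per-group R^2:
    ``R^2 = v / (v + noise_sd^2)`` with signal variance
    ``v = (lead_weight^2 + 2) * baseline_sd^2``.  The defaults give
    R^2 ~ 0.05 in the reference group and ~ 0.95 in the contrast group.
    """

    count: int = 0
    noise_sd_group1: float = 14.5
    noise_sd_group2: float = 0.76
    lead_weight: float = 3.0

    @property
    def probes_used(self) -> int:
        return 4 * self.count


@dataclass
class SyntheticConfig:
    n_probes: int = 2000
    n_group1: int = 42
    n_group2: int = 71
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    mean_shift: MeanShiftBlock = field(default_factory=MeanShiftBlock)
    shape_shift: ShapeShiftBlock = field(default_factory=ShapeShiftBlock)
    entropy_shift: EntropyShiftBlock = field(default_factory=EntropyShiftBlock)
    modules: ModuleBlock = field(default_factory=ModuleBlock)
    quadruplets: QuadrupletBlock = field(default_factory=QuadrupletBlock)
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ConfigurationError("n_probes must be positive")
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ConfigurationError("each group needs at least 2 samples")
        if self.baseline_sd <= 0:
            raise ConfigurationError("baseline_sd must be positive")
        planted = (
            self.mean_shift.count
            + self.shape_shift.count
            + self.entropy_shift.count
            + self.modules.count
            + self.quadruplets.probes_used
        )
        if planted > self.n_probes:
            raise ConfigurationError(
                f"planted blocks need {planted} probes but n_probes={self.n_probes}"
            )
        if not (0 <= self.mean_shift.fraction_up <= 1):
            raise ConfigurationError("fraction_up must be in [0, 1]")
        if self.shape_shift.variance_ratio <= 0:
            raise ConfigurationError("variance_ratio must be positive")
        if self.entropy_shift.dispersion_ratio <= 0:
            raise ConfigurationError("dispersion_ratio must be positive")
        for rho in (
            self.modules.within_correlation_group1,
            self.modules.within_correlation_group2,
        ):
            if not (0 <= rho < 1):
                raise ConfigurationError("within-module correlation must be in [0, 1)")
        if self.quadruplets.count and (
            self.quadruplets.noise_sd_group1 <= 0
            or self.quadruplets.noise_sd_group2 <= 0
        ):
            raise ConfigurationError("quadruplet noise SDs must be positive")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``labels`` maps each probe to its planted class (``none``,
    ``mean_shift_up``, ``mean_shift_down``, ``shape_shift``,
    ``entropy_shift``, ``module:<k>``, ``quadruplet:<k>``); labels are
    mutually exclusive.  ``modules`` records the expected within-module
    correlation per group; ``quadruplets`` the probe roles and expected
    per-group R^2.
    """

    labels: pd.Series
    modules: list[dict]
    quadruplets: list[dict]

    def probes_with_label(self, prefix: str) -> pd.Index:
        return self.labels.index[self.labels.str.startswith(prefix)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"probe_id": self.labels.index, "label": self.labels.values})


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

_STREAMS = {
    "background": 0,
    "mean_shift": 1,
    "shape_shift": 2,
    "entropy_shift": 3,
    "modules": 4,
    "quadruplets": 5,
}


def _rng(seed: int, block: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[block]])


def module_loading(rho: float) -> float:
    """Latent-factor loading giving pairwise correlation ``rho`` with unit
    idiosyncratic noise: rho = a^2/(a^2+1)  =>  a = sqrt(rho/(1-rho))."""
    if not (0 <= rho < 1):
        raise ConfigurationError("correlation must be in [0, 1)")
    return math.sqrt(rho / (1.0 - rho))


def expected_quadruplet_r2(block: QuadrupletBlock, baseline_sd: float, group: int) -> float:
    v = (block.lead_weight**2 + 2.0) * baseline_sd**2
    noise = block.noise_sd_group1 if group == 1 else block.noise_sd_group2
    return v / (v + noise**2)


def expected_seed_pair_correlation(
    block: QuadrupletBlock, baseline_sd: float, group: int
) -> float:
    """Expected corr(probe1, probe2) of a planted quadruplet in one group."""
    w = block.lead_weight
    noise = block.noise_sd_group1 if group == 1 else block.noise_sd_group2
    return w * baseline_sd / math.sqrt((w**2 + 2.0) * baseline_sd**2 + noise**2)


def generate_dataset(config: SyntheticConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a two-group dataset with the configured planted blocks.

    Deterministic for a fixed ``config.seed``.  Background probes are i.i.d.
    Gaussian with identical distribution in both groups; each planted block
    overwrites its own rows using an independent random stream.
    """
    config.validate()
    p, n1, n2 = config.n_probes, config.n_group1, config.n_group2
    n = n1 + n2
    mu, sd = config.baseline_mean, config.baseline_sd

    probe_ids = [f"P{i:06d}" for i in range(p)]
    sample_ids = [f"N{i:03d}" for i in range(n1)] + [f"P{i:03d}" for i in range(n2)]
    groups = pd.Series(
        [REFERENCE_GROUP] * n1 + [CONTRAST_GROUP] * n2, index=sample_ids, name="group"
    )

    # background fills the whole matrix; planted rows are overwritten below
    values = _rng(config.seed, "background").normal(mu, sd, size=(p, n))
    labels = np.array(["none"] * p, dtype=object)
    g1 = slice(0, n1)
    g2 = slice(n1, n)

    row = 0

    # mean shifts: contrast-group location moves by effect_size * sd
    ms = config.mean_shift
    if ms.count:
        rng = _rng(config.seed, "mean_shift")
        block = rng.normal(mu, sd, size=(ms.count, n))
        n_up = int(round(ms.count * ms.fraction_up))
        shift = np.where(np.arange(ms.count) < n_up, 1.0, -1.0) * ms.effect_size * sd
        block[:, g2] += shift[:, None]
        values[row : row + ms.count] = block
        labels[row : row + n_up] = "mean_shift_up"
        labels[row + n_up : row + ms.count] = "mean_shift_down"
        row += ms.count

    # shape shifts: equal mean, contrast variance multiplied
    ss = config.shape_shift
    if ss.count:
        rng = _rng(config.seed, "shape_shift")
        block = rng.normal(mu, sd, size=(ss.count, n))
        block[:, g2] = mu + (block[:, g2] - mu) * math.sqrt(ss.variance_ratio)
        values[row : row + ss.count] = block
        labels[row : row + ss.count] = "shape_shift"
        row += ss.count

    # entropy shifts: equal mean, contrast drawn uniform over a wide range
    es = config.entropy_shift
    if es.count:
        rng = _rng(config.seed, "entropy_shift")
        block = rng.normal(mu, sd, size=(es.count, n))
        half = math.sqrt(3.0) * es.dispersion_ratio * sd
        block[:, g2] = rng.uniform(mu - half, mu + half, size=(es.count, n2))
        values[row : row + es.count] = block
        labels[row : row + es.count] = "entropy_shift"
        row += es.count

    # correlated modules via a shared latent factor per module per group
    mb = config.modules
    module_truth: list[dict] = []
    if mb.n_modules:
        rng = _rng(config.seed, "modules")
        loadings = (
            module_loading(mb.within_correlation_group1),
            module_loading(mb.within_correlation_group2),
        )
        for k in range(mb.n_modules):
            block = np.empty((mb.module_size, n))
            for a, sl, size in ((loadings[0], g1, n1), (loadings[1], g2, n2)):
                z = rng.normal(size=size)  # latent factor, one value per sample
                e = rng.normal(size=(mb.module_size, size))
                block[:, sl] = mu + sd * (a * z[None, :] + e) / math.sqrt(a**2 + 1.0)
            values[row : row + mb.module_size] = block
            probes = probe_ids[row : row + mb.module_size]
            labels[row : row + mb.module_size] = f"module:{k}"
            module_truth.append(
                {
                    "id": k,
                    "probes": list(probes),
                    "rho_group1": mb.within_correlation_group1,
                    "rho_group2": mb.within_correlation_group2,
                }
            )
            row += mb.module_size

    # quadruplets: probe1 = weighted sum of probes 2-4 plus per-group noise
    qb = config.quadruplets
    quad_truth: list[dict] = []
    if qb.count:
        rng = _rng(config.seed, "quadruplets")
        w = qb.lead_weight
        norm = math.sqrt(w**2 + 2.0)
        for k in range(qb.count):
            regs = rng.normal(mu, sd, size=(3, n))  # probes 2, 3, 4
            signal = (w * (regs[0] - mu) + (regs[1] - mu) + (regs[2] - mu)) / norm
            eps = np.empty(n)
            eps[g1] = rng.normal(0.0, qb.noise_sd_group1 / norm, size=n1)
            eps[g2] = rng.normal(0.0, qb.noise_sd_group2 / norm, size=n2)
            p1 = mu + signal + eps
            values[row : row + 4] = np.vstack([p1, regs])
            probes = probe_ids[row : row + 4]
            labels[row : row + 4] = f"quadruplet:{k}"
            quad_truth.append(
                {
                    "id": k,
                    "regressand": probes[0],
                    "regressors": list(probes[1:]),
                    "r2_group1": expected_quadruplet_r2(qb, sd, 1),
                    "r2_group2": expected_quadruplet_r2(qb, sd, 2),
                }
            )
            row += 4

    ds = ExpressionDataset(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
        groups,
    )
    truth = GroundTruth(
        labels=pd.Series(labels, index=ds.probe_ids, name="label"),
        modules=module_truth,
        quadruplets=quad_truth,
    )
    return ds, truth


def study_config(n_probes: int = 2000, seed: int = 0, **overrides) -> SyntheticConfig:
    """The default planted-effects configuration used by the analysis scripts:
    5% mean shifts (1 SD), 5% shape shifts (variance x3), 5% entropy shifts,
    five 10-probe modules correlated only in the contrast group (rho 0.9), and
    ten planted quadruplets."""
    frac = n_probes / 2000
    cfg = SyntheticConfig(
        n_probes=n_probes,
        mean_shift=MeanShiftBlock(count=max(1, int(100 * frac))),
        shape_shift=ShapeShiftBlock(count=max(1, int(100 * frac))),
        entropy_shift=EntropyShiftBlock(count=max(1, int(100 * frac))),
        modules=ModuleBlock(n_modules=5, module_size=10),
        quadruplets=QuadrupletBlock(count=10),
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def null_config(n_probes: int = 2000, seed: int = 0) -> SyntheticConfig:
    """All block counts zero: both groups drawn from one distribution."""
    return SyntheticConfig(n_probes=n_probes, seed=seed)
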
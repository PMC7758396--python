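"""Synthetic urinary-qPCR cohort generator.

Emulates a two-group study on the normalized CtS expression scale
(CtS = Ct(gene)/Ct(beta-actin), reported x1000): per-gene group mean shifts,
within-group multivariate Gaussian noise with an exchangeable gene-gene
correlation, and — one level below — raw instrument-like Ct readings in
replicate, produced by inverting the normalization through a simulated
beta-actin reference channel.

The default configuration encodes the study conditions of the risk-
stratification cohort: 149 higher-risk vs 53 lower-risk patients, the nine
reported group mean differences (CST3 +1008 ... PTEN -121 on the x1000
scale), and five further genes with a deliberately borderline effect
(|shift| = 60, noise scaled so a two-sample t-test at the default group
sizes is non-significant about half the time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .panels import (
    BENIGN, CANCER, HIGHER_RISK, LOWER_RISK, PANEL14, REFERENCE_GENE, GenePanel,
)

__all__ = [
    "SimConfig",
    "default_config",
    "simulate_profiles",
    "profiles_to_raw_ct",
    "DELTA_DEFAULTS",
]

# Reported group mean differences (group A minus group B) on the x1000 CtS
# scale for the nine significantly shifted genes.
DELTA_SIGNIFICANT = {
    "CST3": 1008.0,
    "VEGFA": 953.0,
    "GOLM1": 813.0,
    "CCND1": 727.0,
    "LMTK2": 552.0,
    "PMP22": 534.0,
    "TMPRSS2": 523.0,
    "PIP5K1A": -274.0,
    "PTEN": -121.0,
}

# The remaining five genes shift without reaching significance at the
# default group sizes. Magnitude 60 with matched noise (below) puts a
# two-sample t-test right at the alpha=0.05 boundary; signs are arbitrary
# (ANXA3 and GSTP1 chosen negative).
DELTA_BORDERLINE = {
    "CDK1": 60.0,
    "EZH2": 60.0,
    "PCA3": 60.0,
    "ANXA3": -60.0,
    "GSTP1": -60.0,
}

DELTA_DEFAULTS = {**DELTA_SIGNIFICANT, **DELTA_BORDERLINE}

#: Default within-group SD (x1000 CtS scale) for the nine significant genes:
#: ~11% CV at mid-scale, small enough that the whole Gaussian mass stays in
#: the physically meaningful positive-CtS range.
SIGMA_SIGNIFICANT = 120.0


def _borderline_sigma(n_a: int = 149, n_b: int = 53, delta: float = 60.0) -> float:
    """SD making a |delta| shift sit at the t-test significance boundary.

    Solves E[t] = z_{0.975} for a two-sample test at the default group
    sizes, so roughly half of simulated cohorts call the gene significant.
    """
    return delta / (1.96 * math.sqrt(1.0 / n_a + 1.0 / n_b))


def _as_gene_series(value, panel: GenePanel, name: str) -> pd.Series:
    """Broadcast a scalar or per-gene mapping onto panel order."""
    if np.isscalar(value):
        return pd.Series(float(value), index=list(panel), name=name)
    ser = pd.Series(dict(value), dtype=float, name=name)
    missing = [g for g in panel if g not in ser.index]
    if missing:
        raise ValueError(f"{name} missing genes: {missing}")
    return ser.reindex(list(panel))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one simulated two-group cohort.

    Per-gene fields (``mu_b``, ``delta``, ``sigma``) accept either a scalar
    (broadcast over the panel) or a gene -> value mapping; they live on the
    x1000 CtS scale. ``label_a``/``label_b`` name the two groups
    (higher/lower risk by default; cancer/benign for the diagnosis task).
    """

    panel: GenePanel = PANEL14
    n_group_a: int = 149
    n_group_b: int = 53
    mu_b: Mapping[str, float] | float = 1100.0
    delta: Mapping[str, float] | float = 0.0
    sigma: Mapping[str, float] | float = SIGMA_SIGNIFICANT
    correlation: float = 0.0
    actin_ct_mean: float = 25.0
    actin_ct_sd: float = 1.5
    replicate_sd: float = 0.15
    n_replicates: int = 3
    label_a: str = HIGHER_RISK
    label_b: str = LOWER_RISK
    seed: int = 0

    # -- derived, validated views -------------------------------------
    def mu_b_series(self) -> pd.Series:
        return _as_gene_series(self.mu_b, self.panel, "mu_b")

    def delta_series(self) -> pd.Series:
        return _as_gene_series(self.delta, self.panel, "delta")

    def sigma_series(self) -> pd.Series:
        return _as_gene_series(self.sigma, self.panel, "sigma")

    def validate(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("group sizes must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        sigma = self.sigma_series()
        if not (sigma > 0).all():
            bad = list(sigma.index[sigma <= 0])
            raise ValueError(f"sigma must be > 0 for all genes; offending: {bad}")
        p = len(self.panel)
        lo = -1.0 / (p - 1) if p > 1 else -1.0
        if not (lo < self.correlation < 1.0):
            raise ValueError(
                f"correlation {self.correlation} makes the implied covariance "
                f"non-positive-definite (admissible range ({lo:.4f}, 1) for "
                f"{p} genes)"
            )

    def covariance(self) -> np.ndarray:
        """Within-group covariance on the x1000 CtS scale."""
        sigma = self.sigma_series().to_numpy()
        p = sigma.size
        corr = np.full((p, p), self.correlation)
        np.fill_diagonal(corr, 1.0)
        return corr * np.outer(sigma, sigma)

    def with_(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a config from a flat YAML mapping (panel given as 14/8/6)."""
        from .panels import get_panel

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "panel" in raw:
            raw["panel"] = get_panel(raw["panel"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)


def default_config(task: str = "stratification", seed: int = 0, **overrides) -> SimConfig:
    """Build the calibrated default cohort configuration.

    ``stratification``: 149 higher-risk vs 53 lower-risk, the nine reported
    mean differences plus five borderline shifts. ``diagnosis``: 202 cancer
    vs 191 benign with half-size shifts (no reported effect sizes exist for
    the benign contrast; the defaults are an arbitrary, documented choice).

    Baselines ``mu_b`` are centred so both group means sit mid-range of the
    admissible CtS band implied by a 25-cycle actin reference.
    """
    delta = dict(DELTA_DEFAULTS)
    sigma = {g: SIGMA_SIGNIFICANT for g in DELTA_SIGNIFICANT}
    sigma.update({g: _borderline_sigma() for g in DELTA_BORDERLINE})
    if task == "diagnosis":
        delta = {g: 0.5 * d for g, d in delta.items()}
        base = dict(
            n_group_a=202, n_group_b=191, label_a=CANCER, label_b=BENIGN,
        )
    elif task == "stratification":
        base = {}
    else:
        raise ValueError(f"unknown task {task!r}")
    mu_b = {g: 1100.0 - delta[g] / 2.0 for g in delta}
    cfg = SimConfig(mu_b=mu_b, delta=delta, sigma=sigma, seed=seed, **base)
    return cfg.with_(**overrides) if overrides else cfg


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent child streams so profile and raw-Ct noise never interleave
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_profiles(config: SimConfig) -> pd.DataFrame:
    """Draw a cohort of per-patient normalized expression profiles.

    Returns a DataFrame indexed by patient id with one column per panel
    gene (CtS on the x1000 scale) plus a ``label`` column. Group A rows
    come first. Deterministic given ``config.seed``.
    """
    config.validate()
    genes = list(config.panel)
    mu_b = config.mu_b_series().to_numpy()
    delta = config.delta_series().to_numpy()
    cov = config.covariance()
    rng = _rng(config, stream=1)

    blocks, labels = [], []
    for mean, n, label in (
        (mu_b + delta, config.n_group_a, config.label_a),
        (mu_b, config.n_group_b, config.label_b),
    ):
        blocks.append(
            rng.multivariate_normal(mean, cov, size=n, method="cholesky")
        )
        labels.extend([label] * n)
    values = np.vstack(blocks)
    if (values <= 0).any():
        raise ValueError(
            "simulation produced non-positive CtS values; the configured "
            "means/SDs put Gaussian mass at CtS <= 0 (pathological config)"
        )
    index = pd.Index(
        [f"P{i + 1:05d}" for i in range(values.shape[0])], name="patient_id"
    )
    out = pd.DataFrame(values, columns=genes, index=index)
    out["label"] = labels
    return out


def profiles_to_raw_ct(profiles: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Invert the normalization: emit replicate-level raw Ct readings.

    Per patient an actin reference Ct is drawn, each gene's true cycle
    threshold is set to (CtS/1000) * actin Ct (CtS is a ratio, so the raw
    channel is multiplicative through the reference), and ``n_replicates``
    readings per gene — and for the actin channel itself — are emitted with
    additive technical noise of ``replicate_sd`` cycles.

    Returns a long DataFrame with columns patient_id, gene, replicate, ct.
    """
    config.validate()
    genes = list(config.panel)
    missing = [g for g in genes if g not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack panel genes: {missing}")
    rng = _rng(config, stream=2)

    n_pat = len(profiles)
    actin_true = rng.normal(config.actin_ct_mean, config.actin_ct_sd, size=n_pat)
    cts = profiles[genes].to_numpy(dtype=float)
    true_ct = np.column_stack([(cts / 1000.0) * actin_true[:, None], actin_true])
    if (true_ct <= 0).any():
        raise ValueError(
            "implied raw Ct <= 0; actin/CtS configuration is pathological"
        )

    n_chan = len(genes) + 1
    reps = np.arange(1, config.n_replicates + 1)
    noise = rng.normal(
        0.0, config.replicate_sd, size=(n_pat, n_chan, config.n_replicates)
    ) if config.replicate_sd > 0 else np.zeros((n_pat, n_chan, config.n_replicates))
    readings = true_ct[:, :, None] + noise
    if (readings <= 0).any():
        raise ValueError("replicate noise produced a reading with Ct <= 0")

    patient_ids = profiles.index.to_numpy()
    out = pd.DataFrame(
        {
            "patient_id": np.repeat(patient_ids, n_chan * config.n_replicates),
            "gene": np.tile(
                np.repeat(genes + [REFERENCE_GENE], config.n_replicates), n_pat
            ),
            "replicate": np.tile(reps, n_pat * n_chan),
            "ct": readings.reshape(-1),
        }
    )
    return out
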
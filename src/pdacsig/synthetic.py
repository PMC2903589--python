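"""Synthetic two-cohort expression studies with censored survival outcomes.

The generator emulates the structure the pipeline assumes: two cohorts of
matched tumor-normal pairs profiled under different conditions (a systematic
per-gene batch offset separates them), a small set of genes truly
differential between nonmetastatic and metastatic tumors, and validation
cohorts whose survival hazard depends on each sample's correlation to a
signature centroid.  Values are log2 ratios with additive Gaussian noise,
the standard model for two-color array data.

Everything is driven by a single :class:`SimConfig`; identical config and
seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifier import Centroid
from .survival import SurvivalRecord

__all__ = ["SimConfig", "SimulatedStudy", "simulate_derivation_sets", "simulate_validation_cohort"]

LOW, HIGH = "low", "high"


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults mirror a two-cohort derivation design of 15 tumor-normal pairs
    per cohort with a 6-gene signal, survival on a months scale with a
    low-risk median near 4 years, a four-fold hazard for high-risk samples,
    and ~30% censoring.
    """

    n_genes: int = 1000
    n_per_class: int = 15
    n_de_genes: int = 6
    effect_size: float = 1.5  # mean log2-ratio shift of differential genes
    batch_shift: float = 1.0  # sd of the per-gene cohort offset
    noise_sd: float = 0.5
    baseline_hazard: float = float(np.log(2) / 49.0)  # events per month (low risk)
    hazard_ratio_true: float = 4.0
    censor_rate: float = 0.3
    missing_rate: float = 0.02  # completely-at-random missingness
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_per_class < 1:
            raise ValueError("n_genes and n_per_class must be positive")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError(
                f"n_de_genes={self.n_de_genes} must lie in [0, n_genes={self.n_genes}]"
            )
        for name in ("effect_size", "batch_shift", "noise_sd", "baseline_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.hazard_ratio_true <= 0:
            raise ValueError("hazard_ratio_true must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class SimulatedStudy:
    """A generated study: expression, annotation, survival, and the truth.

    annotation has one row per expression column with columns sample_id,
    batch, tissue, outcome.  survival has columns sample_id, time_months,
    event (tumor samples only).  truth records what was planted: the row
    indices and signed shifts of the differential genes, and per-sample true
    risk labels.
    """

    expression: pd.DataFrame
    annotation: pd.DataFrame
    survival: pd.DataFrame
    de_gene_indices: np.ndarray
    de_gene_signs: np.ndarray = field(default_factory=lambda: np.array([]))
    risk_labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self):
        if list(self.annotation["sample_id"]) != list(self.expression.columns):
            raise ValueError("annotation rows must match expression columns one-to-one")
        if self.de_gene_indices.size and self.de_gene_indices.max() >= self.expression.shape[0]:
            raise ValueError("truth gene indices outside the matrix")

    @property
    def de_genes(self) -> list:
        return [self.expression.index[i] for i in self.de_gene_indices]

    def survival_records(self, sample_ids=None) -> list[SurvivalRecord]:
        tab = self.survival
        if sample_ids is not None:
            tab = tab.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return [
            SurvivalRecord(time=row.time_months, event=bool(row.event))
            for row in tab.itertuples()
        ]


def _draw_survival(rng, hazards: np.ndarray, censor_rate: float):
    """Exponential event times with independent exponential censoring.

    The censoring rate c_i = h_i * q/(1-q) makes P(censored) = q exactly for
    every sample regardless of its own hazard h_i.
    """
    t_event = rng.exponential(1.0 / hazards)
    if censor_rate == 0:
        return t_event, np.ones(hazards.shape[0], dtype=bool)
    c_rate = hazards * censor_rate / (1.0 - censor_rate)
    t_cens = rng.exponential(1.0 / c_rate)
    time = np.minimum(t_event, t_cens)
    return time, t_event <= t_cens


def _inject_missing(rng, values: np.ndarray, rate: float) -> np.ndarray:
    if rate == 0:
        return values
    mask = rng.random(values.shape) < rate
    # never blank out an entire gene row
    full_rows = mask.all(axis=1)
    mask[full_rows, 0] = False
    out = values.copy()
    out[mask] = np.nan
    return out


def simulate_derivation_sets(config: SimConfig) -> SimulatedStudy:
    """Generate the two-cohort derivation design with matched normals.

    Cohort A holds nonmetastatic tumors, cohort B metastatic tumors; each
    cohort also carries matched normal samples.  Every cohort-B sample
    (tumor and normal) receives a per-gene batch offset drawn once per gene
    with sd ``batch_shift``; only cohort-B *tumors* additionally receive the
    class effect of magnitude ``effect_size`` on the differential genes, with
    random sign per gene.
    """
    rng = np.random.default_rng([config.seed, 1])
    g, n = config.n_genes, config.n_per_class
    genes = config.gene_ids()

    groups = [("A", "tumor"), ("A", "normal"), ("B", "tumor"), ("B", "normal")]
    sample_ids = [f"{b}_{t[0].upper()}{i + 1:02d}" for b, t in groups for i in range(n)]
    batch = np.repeat([b for b, _ in groups], n)
    tissue = np.repeat([t for _, t in groups], n)

    values = config.noise_sd * rng.standard_normal((g, 4 * n))
    offset = config.batch_shift * rng.standard_normal(g)
    values[:, batch == "B"] += offset[:, None]

    de_idx = np.sort(rng.choice(g, size=config.n_de_genes, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    b_tumor = (batch == "B") & (tissue == "tumor")
    values[np.ix_(de_idx, np.flatnonzero(b_tumor))] += (
        config.effect_size * signs[:, None]
    )

    values = _inject_missing(rng, values, config.missing_rate)

    outcome = np.where(
        tissue == "normal", "normal", np.where(batch == "A", "nonmetastatic", "metastatic")
    )
    annotation = pd.DataFrame(
        {"sample_id": sample_ids, "batch": batch, "tissue": tissue, "outcome": outcome}
    )

    tumor_mask = tissue == "tumor"
    hazards = np.where(
        batch[tumor_mask] == "B",
        config.baseline_hazard * config.hazard_ratio_true,
        config.baseline_hazard,
    )
    time, event = _draw_survival(rng, hazards, config.censor_rate)
    survival = pd.DataFrame(
        {
            "sample_id": np.asarray(sample_ids)[tumor_mask],
            "time_months": time,
            "event": event.astype(int),
        }
    )
    risk = pd.Series(
        np.where(batch[tumor_mask] == "B", HIGH, LOW),
        index=np.asarray(sample_ids)[tumor_mask],
        name="risk",
    )

    return SimulatedStudy(
        expression=pd.DataFrame(values, index=genes, columns=sample_ids),
        annotation=annotation,
        survival=survival,
        de_gene_indices=de_idx,
        de_gene_signs=signs,
        risk_labels=risk,
    )


def simulate_validation_cohort(
    config: SimConfig,
    centroid: Centroid,
    n_samples: int | None = None,
    prefix: str = "V",
) -> SimulatedStudy:
    """Generate an independent tumor cohort scored against a centroid.

    Each sample carries a latent orientation: its signature-gene profile is
    the standardized centroid deviation scaled by ``effect_size``, with a
    random +/- sign, plus noise.  The *true* risk label is then assigned from
    the realized Pearson correlation to the centroid (r > 0 low risk,
    otherwise high risk), and survival is exponential with hazard
    ``baseline_hazard * hazard_ratio_true**is_high``.
    """
    if len(centroid.genes) == 0:
        raise ValueError("empty centroid")
    gene_ids = config.gene_ids()
    missing = set(centroid.genes) - set(gene_ids)
    if missing:
        raise ValueError(f"centroid genes not in the simulated gene list: {sorted(missing)}")

    rng = np.random.default_rng([config.seed, 2])
    n = n_samples if n_samples is not None else 2 * config.n_per_class
    g = config.n_genes
    sample_ids = [f"{prefix}{i + 1:03d}" for i in range(n)]

    values = config.noise_sd * rng.standard_normal((g, n))
    dev = centroid.values.to_numpy(dtype=float)
    dev = dev - dev.mean()
    sd = dev.std()
    unit = dev / sd if sd > 0 else np.zeros_like(dev)
    orient = rng.choice([-1.0, 1.0], size=n)
    rows = [gene_ids.index(gg) for gg in centroid.genes]
    values[np.ix_(rows, range(n))] += config.effect_size * np.outer(unit, orient)

    # truth from the realized correlation, exactly as the classifier sees it
    sig = values[rows, :]
    r = np.zeros(n)
    c = centroid.values.to_numpy(dtype=float)
    for j in range(n):
        x = sig[:, j]
        if x.std() == 0 or c.std() == 0:
            r[j] = 0.0
        else:
            r[j] = np.corrcoef(x, c)[0, 1]
    risk = pd.Series(np.where(r > 0, LOW, HIGH), index=sample_ids, name="risk")

    hazards = config.baseline_hazard * np.where(
        risk.to_numpy() == HIGH, config.hazard_ratio_true, 1.0
    )
    time, event = _draw_survival(rng, hazards, config.censor_rate)

    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "batch": prefix,
            "tissue": "tumor",
            "outcome": "unknown",
        }
    )
    survival = pd.DataFrame(
        {"sample_id": sample_ids, "time_months": time, "event": event.astype(int)}
    )
    return SimulatedStudy(
        expression=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        annotation=annotation,
        survival=survival,
        de_gene_indices=np.array(rows),
        risk_labels=risk,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
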
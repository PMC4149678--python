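"""Synthetic multi-batch GC-MS experiment generator.

The generator reproduces the acquisition structure of a batched GC-MS
phenotyping campaign so every normalization operator and diagnostic can be
exercised against known ground truth:

* each batch holds a fixed panel of test entries (genotypes) with biological
  replicates, plus one pooled reference sample injected twice — at the
  middle and at the end of the batch run;
* observed intensity = true concentration x dry weight x per-metabolite
  batch factor x run-order drift x column-change step x multiplicative
  log-normal noise;
* the internal-standard channel shares the run-level drift but not the
  metabolite-specific batch factors — encoding the reason IS normalization
  alone cannot remove analyte-specific batch effects;
* measurement noise is concentration-dependent: CV = cv_base +
  cv_low_abundance / sqrt(baseline abundance), the simplest monotone form
  giving low-abundance analytes higher relative noise.

Batch factors have a shared batch-level component (instrument sensitivity
drifts batch to batch for all analytes in the same direction) plus a
metabolite-specific component; ``batch_correlation`` sets the split while
the marginal per-metabolite log-sd stays ``sigma_batch``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from refnorm.core_data import (
    BatchLayout,
    IntensityMatrix,
    SampleRecord,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_experiment",
    "truth_ratio_matrix",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated acquisition campaign.

    Defaults mirror the study scale this simulator emulates, reduced for
    speed: 98 metabolites over 6 batches, each batch carrying the same 5
    entries x 2 replicates plus a reference injected at the middle and end
    of the batch run.
    """

    n_metabolites: int = 98
    n_batches: int = 6
    entries_per_batch: int = 5
    replicates_per_entry: int = 2
    # baseline abundance across metabolites: log10-normal, roughly 4 orders
    # of magnitude, on a scale relative to the internal standard
    abundance_log10_mean: float = 2.0
    abundance_log10_sd: float = 1.0
    sigma_bio: float = 0.4  # sd of per-entry log-fold biological effects
    sigma_batch: float = 0.3  # marginal sd of per-metabolite log batch factors
    batch_correlation: float = 0.5  # shared fraction of batch-factor variance
    drift_rate: float = 0.002  # per-run multiplicative sensitivity decay
    column_change_run: int | None = None  # step applies to runs after this
    column_step_log_sd: float = 0.25  # sd of per-metabolite log step factors
    cv_base: float = 0.10
    cv_low_abundance: float = 0.5  # CV = cv_base + cv_low_abundance/sqrt(abundance)
    is_cv: float = 0.05  # internal-standard channel noise CV
    is_nominal: float = 50_000.0  # nominal IS peak area
    dry_weight_range_mg: tuple[float, float] = (2.5, 3.5)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_metabolites": self.n_metabolites,
            "n_batches": self.n_batches,
            "entries_per_batch": self.entries_per_batch,
            "replicates_per_entry": self.replicates_per_entry,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValidationError(f"{name} must be an integer >= 1, got {v!r}")
        nonneg = {
            "abundance_log10_sd": self.abundance_log10_sd,
            "sigma_bio": self.sigma_bio,
            "sigma_batch": self.sigma_batch,
            "drift_rate": self.drift_rate,
            "column_step_log_sd": self.column_step_log_sd,
            "cv_base": self.cv_base,
            "cv_low_abundance": self.cv_low_abundance,
            "is_cv": self.is_cv,
        }
        for name, v in nonneg.items():
            if not (np.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        if not (0 <= self.batch_correlation <= 1):
            raise ValidationError(
                f"batch_correlation must be in [0, 1], got {self.batch_correlation}"
            )
        lo, hi = self.dry_weight_range_mg
        if not (0 < lo <= hi):
            raise ValidationError(
                f"dry_weight_range_mg must satisfy 0 < lo <= hi, got ({lo}, {hi})"
            )
        if self.is_nominal <= 0:
            raise ValidationError("is_nominal must be > 0")
        if self.column_change_run is not None and self.column_change_run < 1:
            raise ValidationError("column_change_run must be >= 1 or None")

    # -- config file round-trip ---------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dry_weight_range_mg"] = list(self.dry_weight_range_mg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        if "dry_weight_range_mg" in d:
            d = dict(d)
            d["dry_weight_range_mg"] = tuple(d["dry_weight_range_mg"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated matrix.

    ``true_concentration`` is per sample x metabolite on the per-mg scale
    (dry weight, drift and noise excluded); every reference sample shares
    ``reference_concentration`` because references derive from one pooled
    material.  ``batch_factor`` is metabolites x batches, ``drift`` is
    indexed by global run order, ``step_factor`` per metabolite (all ones
    when no column change is simulated).
    """

    true_concentration: pd.DataFrame
    reference_concentration: pd.Series
    batch_factor: pd.DataFrame
    drift: pd.Series
    step_factor: pd.Series
    config: SimulationConfig


def _lognormal_noise(rng: np.random.Generator, sigma, size) -> np.ndarray:
    """Multiplicative noise exp(N(-s^2/2, s)) with mean exactly 1."""
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), size)
    return np.exp(rng.normal(-(sigma**2) / 2.0, sigma, size=size))


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, list[SampleRecord], SimulationTruth]:
    """Generate one acquisition campaign: matrix, metadata and ground truth.

    The run sequence of each batch is: the first half of the test
    injections, one reference injection, the remaining test injections, and
    a closing reference injection.  Identical configs (including seed)
    produce bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_met = config.n_metabolites
    mets = [f"M{j + 1:03d}" for j in range(n_met)]
    entries = [f"E{i + 1}" for i in range(config.entries_per_batch)]

    # metabolite baselines and per-metabolite noise CV
    base = 10.0 ** rng.normal(
        config.abundance_log10_mean, config.abundance_log10_sd, n_met
    )
    with np.errstate(divide="ignore"):
        cv = config.cv_base + config.cv_low_abundance / np.sqrt(base)

    # per-entry biological effects (shared by replicates of the entry)
    entry_effect = np.exp(
        rng.normal(0.0, config.sigma_bio, size=(len(entries), n_met))
    )

    # batch factors: shared batch-level component + metabolite-specific part
    rho = config.batch_correlation
    z_batch = rng.normal(0.0, 1.0, size=config.n_batches)
    e_mb = rng.normal(0.0, 1.0, size=(n_met, config.n_batches))
    log_bf = config.sigma_batch * (
        np.sqrt(rho) * z_batch[None, :] + np.sqrt(1.0 - rho) * e_mb
    )
    batch_ids = [f"B{b + 1:02d}" for b in range(config.n_batches)]
    batch_factor = pd.DataFrame(np.exp(log_bf), index=mets, columns=batch_ids)

    step = (
        np.exp(rng.normal(0.0, config.column_step_log_sd, n_met))
        if config.column_change_run is not None
        else np.ones(n_met)
    )
    step_factor = pd.Series(step, index=mets)

    # build the injection sequence
    n_test = config.entries_per_batch * config.replicates_per_entry
    mid = (n_test + 1) // 2  # reference inserted after this many tests
    records: list[SampleRecord] = []
    sample_plan: list[tuple[str, str, str]] = []  # (sample_id, batch, entry|"")
    run = 0
    for b, batch in enumerate(batch_ids):
        tests = [
            (f"{batch}_{e}_r{r + 1}", e)
            for e in entries
            for r in range(config.replicates_per_entry)
        ]
        seq: list[tuple[str, str, str]] = []
        seq += [(sid, "test", e) for sid, e in tests[:mid]]
        seq += [(f"{batch}_REF_mid", "reference", "")]
        seq += [(sid, "test", e) for sid, e in tests[mid:]]
        seq += [(f"{batch}_REF_end", "reference", "")]
        for sid, role, entry in seq:
            run += 1
            records.append(
                SampleRecord(
                    sample_id=sid,
                    batch_id=batch,
                    run_order=run,
                    role=role,
                    entry=entry,
                    site="",
                    dry_weight_mg=float(
                        rng.uniform(*config.dry_weight_range_mg)
                    ),
                    is_intensity=1.0,  # filled in below
                )
            )
            sample_plan.append((sid, batch, entry))

    n_samples = len(records)
    run_orders = np.array([r.run_order for r in records])
    drift = np.exp(-config.drift_rate * (run_orders - 1).astype(float))
    drift_series = pd.Series(drift, index=run_orders)

    # ground-truth concentrations (per mg)
    entry_idx = {e: i for i, e in enumerate(entries)}
    true_conc = np.empty((n_samples, n_met))
    for i, r in enumerate(records):
        if r.role == "reference":
            true_conc[i] = base
        else:
            true_conc[i] = base * entry_effect[entry_idx[r.entry]]
    sample_ids = [r.sample_id for r in records]
    true_conc_df = pd.DataFrame(true_conc, index=sample_ids, columns=mets)

    # assemble observed intensities
    bf_per_sample = np.stack(
        [batch_factor[r.batch_id].to_numpy() for r in records]
    )
    step_per_sample = np.ones((n_samples, n_met))
    if config.column_change_run is not None:
        past = run_orders > config.column_change_run
        step_per_sample[past] = step
    dw = np.array([r.dry_weight_mg for r in records])
    noise = _lognormal_noise(rng, cv[None, :], (n_samples, n_met))
    observed = (
        true_conc
        * dw[:, None]
        * bf_per_sample
        * drift[:, None]
        * step_per_sample
        * noise
    )
    observed = np.clip(observed, 0.0, None)

    is_noise = _lognormal_noise(rng, config.is_cv, n_samples)
    is_obs = config.is_nominal * drift * is_noise
    records = [
        dataclasses.replace(r, is_intensity=float(v))
        for r, v in zip(records, is_obs)
    ]

    matrix = IntensityMatrix(pd.DataFrame(observed, index=sample_ids, columns=mets))
    truth = SimulationTruth(
        true_concentration=true_conc_df,
        reference_concentration=pd.Series(base, index=mets),
        batch_factor=batch_factor,
        drift=drift_series,
        step_factor=step_factor,
        config=config,
    )
    return matrix, records, truth


def truth_ratio_matrix(truth: SimulationTruth, layout: BatchLayout) -> IntensityMatrix:
    """Exact post-normalization target: true(test)/true(reference) ratios.

    Because every batch's reference injections share one pooled
    concentration vector, the target ratio is the same whichever reference
    a test sample is assigned to; reference rows are exactly 1.  Scaling all
    true concentrations by a constant leaves the ratios unchanged.
    """
    samples = list(truth.true_concentration.index)
    unknown = [s for s in samples if s not in layout.batch_of]
    if unknown:
        raise ValidationError(f"layout does not cover samples: {unknown}")
    ratios = truth.true_concentration.div(truth.reference_concentration, axis=1)
    return IntensityMatrix(ratios)
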
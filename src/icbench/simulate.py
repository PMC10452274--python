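"""Synthetic ICB cohorts with known ground truth.

The generator stands in for curated immunotherapy cohorts: log-normal
TPM-like expression (gene-specific means and dispersions on the log2
scale), a responder fraction defaulting to the 34.2% objective response
rate typical of pooled ICB cohorts, a planted signature whose genes are
shifted by a configurable effect size (in SD units on the log2 scale) in
responders, RECIST categories and PFS drawn so the 6-month stratification
rule reproduces the intended labels, optional paired pre/on-treatment
biopsies with treatment-induced shifts, and survival times whose hazard is
tied to a chosen score. It does not attempt to mimic count overdispersion
or deconvolvable cell-mixture structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix

DEFAULT_RESPONDER_FRACTION = 0.342


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_genes: int = 2000
    n_samples: int = 100
    responder_fraction: float = DEFAULT_RESPONDER_FRACTION
    planted_signature: tuple[str, ...] = ()
    planted_direction: str = "positive"
    effect_size: float = 1.0  # shift in SD units on the log2 scale
    extra_genes: tuple[str, ...] = ()  # e.g. registry genes to include
    noise_sd: float = 1.0  # per-gene SD on the log2 scale
    paired: bool = False
    on_treatment_shift: float = 0.0  # log2-scale shift of planted genes on-Rx
    on_shift_responders_only: bool = False
    survival_beta: float = 0.0  # log-hazard per SD of the linked score
    baseline_hazard: float = 0.05  # events per month
    censoring_rate: float = 0.02  # censoring events per month (0 = none)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValueError("responder_fraction must be in (0, 1)")
        if self.n_genes < 200:
            raise ValueError("n_genes must be >= 200")
        if self.planted_direction not in ("positive", "negative"):
            raise ValueError("planted_direction must be positive/negative")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for audits and power tests."""

    config: SimulationConfig
    responder_samples: tuple[str, ...]
    planted_signature: tuple[str, ...]

    def to_dict(self) -> dict[str, Any]:
        cfg = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in self.config.__dict__.items()
        }
        cfg["planted_signature"] = [str(g) for g in cfg["planted_signature"]]
        cfg["extra_genes"] = [str(g) for g in cfg["extra_genes"]]
        return {
            "config": cfg,
            "responder_samples": [str(s) for s in self.responder_samples],
            "planted_signature": [str(g) for g in self.planted_signature],
        }


def _gene_universe(config: SimulationConfig) -> list[str]:
    names = [f"G{i:05d}" for i in range(config.n_genes)]
    special = list(
        dict.fromkeys(
            [*config.planted_signature, *config.extra_genes]
        )
    )
    if len(special) > config.n_genes:
        raise ValueError("planted signature + extra genes exceed n_genes")
    for i, gene in enumerate(special):
        names[i] = gene.upper()
    missing = set(g.upper() for g in config.planted_signature) - set(names)
    if missing:
        raise ValueError(f"planted signature outside gene universe: {missing}")
    return names


def _expression_block(
    rng: np.random.Generator,
    config: SimulationConfig,
    genes: list[str],
    sample_ids: list[str],
    is_responder: np.ndarray,
) -> pd.DataFrame:
    """Log-normal expression with the planted responder shift applied."""
    n_genes, n_samples = len(genes), len(sample_ids)
    base_mean = rng.normal(3.0, 2.0, size=n_genes)  # log2 scale
    log2 = base_mean[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_genes, n_samples)
    )
    planted = {g.upper() for g in config.planted_signature}
    rows = [i for i, g in enumerate(genes) if g in planted]
    if rows:
        shift = config.effect_size * config.noise_sd
        if config.planted_direction == "negative":
            shift = -shift
        log2[np.ix_(rows, np.flatnonzero(is_responder))] += shift
    tpm = np.maximum(2.0**log2 - 1.0, 0.0)
    return pd.DataFrame(tpm, index=genes, columns=sample_ids)


def _clinical_frame(
    rng: np.random.Generator,
    sample_ids: list[str],
    patient_ids: list[str],
    is_responder: np.ndarray,
    biopsy_time: str = "pre",
    arm: str = "mono",
) -> pd.DataFrame:
    """RECIST + PFS consistent with the 6-month stratification rule."""
    rows = []
    for sid, pid, resp in zip(sample_ids, patient_ids, is_responder):
        if resp:
            category = rng.choice(["CR", "PR", "SD"], p=[0.2, 0.5, 0.3])
            pfs = float(rng.uniform(7.0, 36.0))
        else:
            category = rng.choice(["PD", "SD"], p=[0.75, 0.25])
            pfs = (
                float(rng.uniform(0.5, 5.5))
                if category == "SD"
                else float(rng.uniform(0.5, 12.0))
            )
        rows.append(
            {
                "sample_id": sid,
                "patient_id": pid,
                "response_category": category,
                "pfs_months": round(pfs, 2),
                "pfs_event": 1,
                "biopsy_time": biopsy_time,
                "arm": arm,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, TruthRecord]:
    """One pre-treatment cohort with a planted signature effect."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    n_resp = int(round(config.responder_fraction * config.n_samples))
    is_responder = np.zeros(config.n_samples, dtype=bool)
    is_responder[rng.choice(config.n_samples, size=n_resp, replace=False)] = True
    expr = ExpressionMatrix(
        _expression_block(rng, config, genes, sample_ids, is_responder)
    )
    clin_df = _clinical_frame(
        rng, sample_ids, [f"P{i:04d}" for i in range(config.n_samples)],
        is_responder,
    )
    if config.survival_beta != 0.0 or config.baseline_hazard > 0:
        planted = [g for g in expr.gene_ids
                   if g in {s.upper() for s in config.planted_signature}]
        score = (
            expr.log2p1().values.loc[planted].mean(axis=0)
            if planted
            else pd.Series(0.0, index=sample_ids)
        )
        time, event = simulate_survival(score, config, rng=rng)
        clin_df["os_months"] = np.round(time.to_numpy(), 3)
        clin_df["os_event"] = event.to_numpy()
    clinical = ClinicalTable(clin_df)
    truth = TruthRecord(
        config=config,
        responder_samples=tuple(np.array(sample_ids)[is_responder]),
        planted_signature=tuple(g.upper() for g in config.planted_signature),
    )
    return expr, clinical, truth


def simulate_paired(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, TruthRecord]:
    """Paired pre/on-treatment cohort from the same patients.

    Each patient contributes one pre and one on biopsy; on-treatment
    samples add ``on_treatment_shift`` (log2 scale) to the planted genes,
    optionally in responders only.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config)
    n = config.n_samples
    patient_ids = [f"P{i:04d}" for i in range(n)]
    pre_ids = [f"{p}_PRE" for p in patient_ids]
    on_ids = [f"{p}_ON" for p in patient_ids]
    n_resp = int(round(config.responder_fraction * n))
    is_responder = np.zeros(n, dtype=bool)
    is_responder[rng.choice(n, size=n_resp, replace=False)] = True

    base_mean = rng.normal(3.0, 2.0, size=len(genes))
    patient_effect = rng.normal(0.0, 0.5, size=(len(genes), n))
    planted_rows = [
        i for i, g in enumerate(genes)
        if g in {s.upper() for s in config.planted_signature}
    ]
    blocks = {}
    for label, ids in (("pre", pre_ids), ("on", on_ids)):
        log2 = (
            base_mean[:, None]
            + patient_effect
            + rng.normal(0.0, config.noise_sd, size=(len(genes), n))
        )
        if label == "on" and planted_rows:
            cols = (
                np.flatnonzero(is_responder)
                if config.on_shift_responders_only
                else np.arange(n)
            )
            log2[np.ix_(planted_rows, cols)] += config.on_treatment_shift
        blocks[label] = np.maximum(2.0**log2 - 1.0, 0.0)
    values = pd.DataFrame(
        np.hstack([blocks["pre"], blocks["on"]]),
        index=genes,
        columns=pre_ids + on_ids,
    )
    expr = ExpressionMatrix(values)
    clin_pre = _clinical_frame(rng, pre_ids, patient_ids, is_responder, "pre")
    clin_on = clin_pre.copy()
    clin_on["sample_id"] = on_ids
    clin_on["biopsy_time"] = "on"
    clinical = ClinicalTable(
        pd.concat([clin_pre, clin_on], ignore_index=True)
    )
    truth = TruthRecord(
        config=config,
        responder_samples=tuple(
            np.array(pre_ids + on_ids)[np.tile(is_responder, 2)]
        ),
        planted_signature=tuple(g.upper() for g in config.planted_signature),
    )
    return expr, clinical, truth


def simulate_survival(
    scores: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Exponential survival with hazard proportional to the score.

    Hazard per sample is ``baseline_hazard * exp(beta * z(score))`` with
    ``z`` the within-cohort standardization; independent exponential
    censoring at ``censoring_rate`` (0 means every event is observed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = scores.to_numpy(dtype=float)
    sd = x.std(ddof=0)
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    hazard = config.baseline_hazard * np.exp(config.survival_beta * z)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(
            1.0 / config.censoring_rate, size=len(x)
        )
    else:
        censor_time = np.full(len(x), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return (
        pd.Series(time, index=scores.index, name="time"),
        pd.Series(event, index=scores.index, name="event"),
    )
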
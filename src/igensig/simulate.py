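"""Synthetic cohorts with planted redundant predictive feature blocks.

The generator emulates the two data structures the model exploits:

* **redundancy** — features come in blocks; all features of a block copy
  a latent per-patient Bernoulli driver up to independent flip noise, so
  within-block co-occurrence (Otsuka-Ochiai) is high;
* **transferable co-occurrence** — an unlabeled reference cohort is drawn
  from the same block model without labels, so the reference similarity
  matrix carries the block structure without ever seeing a response.

A subset of blocks is *predictive*: their driver probability depends on
the response label.  Half of them (rounded) are oriented toward
resistance — the carriage pair is applied with the roles swapped — so
the cohort carries both a sensitive and a resistant signature, matching
the two-class structure the model scores.  The remaining background
blocks fire at a label-independent rate.  The truth record lists the
planted predictive feature ids and orientations so recovery can be
measured.

Feature-error injection mirrors a sequencing-noise robustness protocol:
false negatives clear each set bit independently at the given rate;
false positives add bits with the rate normalized to the current set-bit
count (binary genomic matrices are sparse, so naive per-zero flipping
would swamp the signal rather than resemble miscalls).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix

__all__ = ["SimConfig", "ErrorSpec", "generate_cohorts", "inject_errors"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults model a neoadjuvant-trial-sized labeled cohort (200
    patients, balanced pCR) against a large unlabeled tumor reference
    (1,000), with 40 feature blocks of 25 features each, 8 of them
    predictive with a strong carriage contrast (0.7 vs 0.2) and 5%
    per-feature flip noise.
    """

    n_patients: int = 200
    n_reference: int = 1000
    n_blocks: int = 40
    block_size: int = 25
    n_predictive_blocks: int = 8
    p_given_pcr: float = 0.7
    p_given_non_pcr: float = 0.2
    resistant_fraction: float = 0.5  # share of predictive blocks oriented to resistance
    background_rate: float = 0.3
    feature_flip: float = 0.05
    label_balance: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        probs = (
            self.p_given_pcr, self.p_given_non_pcr, self.background_rate,
            self.feature_flip, self.label_balance, self.resistant_fraction,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if min(self.n_patients, self.n_reference, self.n_blocks, self.block_size) < 1:
            raise ValueError("sizes must be >= 1")
        if not 0 <= self.n_predictive_blocks <= self.n_blocks:
            raise ValueError("n_predictive_blocks must be in [0, n_blocks]")


@dataclass(frozen=True)
class ErrorSpec:
    """Feature-error injection: rate, direction and a dedicated seed."""

    rate: float
    mode: str = "both"  # false_positive | false_negative | both
    target: str = "validation"  # bookkeeping only: which matrix this is meant for
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("false_positive", "false_negative", "both"):
            raise ValueError(f"unknown error mode {self.mode!r}")
        if self.target not in ("train", "validation"):
            raise ValueError(f"unknown error target {self.target!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")
        if self.rate > 0.25:
            warnings.warn("error rate beyond the studied 0-25% range", stacklevel=2)


@dataclass
class TruthRecord:
    """What was planted: predictive feature ids and block assignments."""

    predictive_features: list[str]
    predictive_blocks: list[int]
    resistant_blocks: list[int]  # subset of predictive_blocks with swapped orientation
    block_of_feature: dict[str, int]
    null: bool = False  # True when the effect pair carries no signal
    config: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n", encoding="utf-8")


def _feature_names(cfg: SimConfig) -> list[str]:
    return [
        f"SIM:B{b:03d}_F{i:03d}"
        for b in range(cfg.n_blocks)
        for i in range(cfg.block_size)
    ]


def _block_matrix(drivers: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Expand per-patient block drivers into per-feature columns with flip noise."""
    n = drivers.shape[0]
    cols = np.repeat(drivers, cfg.block_size, axis=1)  # (n, n_blocks*block_size)
    flips = rng.random(cols.shape) < cfg.feature_flip
    return (cols ^ flips).astype(np.uint8)


def generate_cohorts(cfg: SimConfig) -> tuple[FeatureMatrix, pd.Series, FeatureMatrix, TruthRecord]:
    """Draw the labeled cohort, its labels, the reference cohort and truth.

    Deterministic given ``cfg.seed``: the same config reproduces
    bit-identical cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    names = _feature_names(cfg)
    predictive_blocks = list(range(cfg.n_predictive_blocks))
    n_resistant = int(round(cfg.n_predictive_blocks * cfg.resistant_fraction))
    resistant_blocks = predictive_blocks[cfg.n_predictive_blocks - n_resistant :]

    # labeled cohort -----------------------------------------------------
    n_pos = int(round(cfg.n_patients * cfg.label_balance))
    labels_arr = np.zeros(cfg.n_patients, dtype=np.int8)
    labels_arr[:n_pos] = 1
    rng.shuffle(labels_arr)
    patient_ids = [f"PT{i:04d}" for i in range(cfg.n_patients)]
    labels = pd.Series(labels_arr, index=pd.Index(patient_ids, name="patient_id"), name="response")

    driver_p = np.full((cfg.n_patients, cfg.n_blocks), cfg.background_rate)
    for b in predictive_blocks:
        hi, lo = cfg.p_given_pcr, cfg.p_given_non_pcr
        if b in resistant_blocks:
            hi, lo = lo, hi
        driver_p[:, b] = np.where(labels_arr == 1, hi, lo)
    drivers = rng.random(driver_p.shape) < driver_p
    labeled = FeatureMatrix(patient_ids, names, _block_matrix(drivers, cfg, rng))

    # unlabeled reference: same block model, label-free (marginal rates) --
    ref_p = np.full((cfg.n_reference, cfg.n_blocks), cfg.background_rate)
    for b in predictive_blocks:
        hi, lo = cfg.p_given_pcr, cfg.p_given_non_pcr
        if b in resistant_blocks:
            hi, lo = lo, hi
        ref_p[:, b] = cfg.label_balance * hi + (1 - cfg.label_balance) * lo
    ref_drivers = rng.random(ref_p.shape) < ref_p
    reference_ids = [f"REF{i:05d}" for i in range(cfg.n_reference)]
    reference = FeatureMatrix(reference_ids, names, _block_matrix(ref_drivers, cfg, rng))

    block_of = {name: i // cfg.block_size for i, name in enumerate(names)}
    predictive_features = [f for f in names if block_of[f] in set(predictive_blocks)]
    truth = TruthRecord(
        predictive_features=predictive_features,
        predictive_blocks=predictive_blocks,
        resistant_blocks=resistant_blocks,
        block_of_feature=block_of,
        null=cfg.p_given_pcr == cfg.p_given_non_pcr,
        config=cfg.__dict__.copy(),
    )
    return labeled, labels, reference, truth


def expected_planted_phi(cfg: SimConfig) -> float:
    """Closed-form expected phi magnitude of a planted feature.

    A planted feature is carried with probability
    p_y = driver_p_y * (1 - flip) + (1 - driver_p_y) * flip given label y;
    for two binary variables phi = (p1 - p0) * sqrt(q (1-q)) / sqrt(pbar (1-pbar))
    with q the label balance and pbar the marginal carriage rate.
    Resistance-oriented blocks have the same magnitude with opposite sign.
    """
    e = cfg.feature_flip
    p1 = cfg.p_given_pcr * (1 - e) + (1 - cfg.p_given_pcr) * e
    p0 = cfg.p_given_non_pcr * (1 - e) + (1 - cfg.p_given_non_pcr) * e
    q = cfg.label_balance
    pbar = q * p1 + (1 - q) * p0
    if pbar in (0.0, 1.0) or q in (0.0, 1.0):
        return 0.0
    return (p1 - p0) * np.sqrt(q * (1 - q)) / np.sqrt(pbar * (1 - pbar))


def inject_errors(fm: FeatureMatrix, spec: ErrorSpec) -> FeatureMatrix:
    """Corrupt a binary feature matrix with false positives/negatives.

    * ``false_negative``: each set bit is cleared independently with
      probability ``rate``.
    * ``false_positive``: each clear bit is set with probability
      ``rate * n_set / n_clear``, so the expected number of added bits is
      ``rate`` times the current set-bit count.
    * ``both``: each direction applied at ``rate / 2``.

    Deterministic given ``spec.seed``; the input matrix is not modified.
    """
    rng = np.random.default_rng(spec.seed)
    inc = fm.incidence.copy()
    if spec.rate == 0:
        return FeatureMatrix(fm.patient_ids, fm.feature_ids, inc)
    fn_rate = {"false_negative": spec.rate, "both": spec.rate / 2}.get(spec.mode, 0.0)
    fp_rate = {"false_positive": spec.rate, "both": spec.rate / 2}.get(spec.mode, 0.0)
    set_mask = inc == 1
    n_set = int(set_mask.sum())
    n_clear = inc.size - n_set
    u = rng.random(inc.shape)
    if fn_rate and n_set:
        inc[set_mask & (u < fn_rate)] = 0
    if fp_rate and n_clear and n_set:
        p_add = min(1.0, fp_rate * n_set / n_clear)
        inc[~set_mask & (u < p_add)] = 1
    return FeatureMatrix(fm.patient_ids, fm.feature_ids, inc)
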
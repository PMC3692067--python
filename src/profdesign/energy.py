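"""The four-term evolutionary design energy and its Z-score normalization.

A decoy sequence is scored by a linear combination of four per-residue
normalized cost terms, each lower-is-better:

* ``e_profile`` — negative mean position-specific log-odds of the decoy
  residues under the scaffold's evolutionary profile;
* ``e_ss`` — mean probability mass the sequence-based predictor places
  away from the scaffold's assigned secondary-structure class;
* ``e_ta`` — mean wrapped angular deviation sqrt(dphi^2 + dpsi^2)/180 of
  predicted from assigned backbone torsions (over positions where both
  scaffold angles are defined);
* ``e_sa`` — mean absolute deviation of predicted from assigned relative
  solvent accessibility.

An optional physics term enters through a registered callback. The search
is guided not by the raw energy but by its Z-score against a baseline of
random sequences: Z = (E - mean) / std, with an independently Z-scored
physics term added with weight ``w`` (-2.44 when physics is enabled, 0
otherwise); keeping the two terms separately normalized keeps both
dimensionless.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Optional, Tuple

import numpy as np
import yaml

from ._data import SS_CLASS_INDEX, decode_sequence, encode_sequence
from ._geom import wrapped_angle_diff
from .features import BasePredictor, FeaturePrediction
from .profile import Profile
from .structio import ScaffoldFeatures

#: Physics-term weight from the design force field when enabled.
PHYSICS_WEIGHT = -2.44

PhysicsScorer = Callable[[str], float]


class EnergyError(ValueError):
    pass


@dataclasses.dataclass
class EnergyComponents:
    """Per-term evolutionary energies (costs; lower is better)."""

    e_profile: float
    e_ss: float
    e_ta: float
    e_sa: float
    e_phys: Optional[float] = None

    def total(self, term_weights=(1.0, 1.0, 1.0, 1.0)) -> float:
        w1, w2, w3, w4 = term_weights
        return (w1 * self.e_profile + w2 * self.e_ss
                + w3 * self.e_ta + w4 * self.e_sa)


@dataclasses.dataclass
class EnergyBaseline:
    """Random-sequence energy statistics used for Z-scoring."""

    mean: float
    std: float
    n: int
    seed: int

    def z(self, energy: float) -> float:
        return (energy - self.mean) / self.std


@dataclasses.dataclass
class DesignConfig:
    """All tunable parameters of a design job, with the standard defaults:
    10 trajectories of 30,000 sweeps at temperature 0.03, a 1,000-sweep
    burn-in, 1,000 random baseline sequences, TM-score thresholds relaxed
    from 0.7 to 0.5 until more than 10 homologs pass, 40% primary-cluster
    expansion, 8 A binding-site radius, and physics weight -2.44 when a
    physics scorer is attached (0 otherwise)."""

    w: float = 0.0
    temperature: float = 0.03
    n_traj: int = 10
    n_sweeps: int = 30000
    burn_in: int = 1000
    n_baseline: int = 1000
    tm_hi: float = 0.7
    tm_lo: float = 0.5
    min_homologs: int = 10
    cluster_frac: float = 0.4
    binding_radius: float = 8.0
    min_len: int = 30
    term_weights: Tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    pseudocount_strength: float = 5.0
    predictor_window: int = 15
    cluster_subsample: int = 20000
    cluster_step: float = 0.25
    max_designs: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 < self.cluster_frac < 1.0:
            raise ValueError("cluster_frac must be in (0, 1)")
        if self.n_sweeps <= self.burn_in:
            raise ValueError("n_sweeps must exceed burn_in")
        if self.n_baseline < 2:
            raise ValueError("n_baseline must be >= 2")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["term_weights"] = list(d["term_weights"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "term_weights" in d:
            d["term_weights"] = tuple(d["term_weights"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def scaffold_feature_arrays(feats: ScaffoldFeatures):
    """Pre-indexed scaffold tracks for energy evaluation: SS class indices,
    torsion arrays with a definedness mask, and the RSA track."""
    ss_idx = np.array([SS_CLASS_INDEX[c] for c in feats.ss])
    defined = np.isfinite(feats.phi) & np.isfinite(feats.psi)
    return ss_idx, feats.phi, feats.psi, defined, feats.rsa


def per_position_terms(seq_idx: np.ndarray, profile: Profile,
                       feats: ScaffoldFeatures, pred_arrays):
    """Per-position contributions of the four terms (before averaging).

    ``pred_arrays`` is the (ss_prob, phi, psi, rsa) tuple of a predictor.
    The torsion row is zero where the scaffold angles are undefined.
    """
    ss_prob, phi_p, psi_p, rsa_p = pred_arrays
    ss_idx, phi_s, psi_s, defined, rsa_s = scaffold_feature_arrays(feats)
    length = len(seq_idx)
    prof_j = -profile.log_odds[np.arange(length), seq_idx]
    ss_j = 1.0 - ss_prob[np.arange(length), ss_idx]
    dphi = wrapped_angle_diff(phi_p, np.where(defined, phi_s, phi_p))
    dpsi = wrapped_angle_diff(psi_p, np.where(defined, psi_s, psi_p))
    ta_j = np.where(defined, np.sqrt(dphi ** 2 + dpsi ** 2) / 180.0, 0.0)
    sa_j = np.abs(rsa_p - rsa_s)
    return prof_j, ss_j, ta_j, sa_j, defined


def evo_energy(seq: str, profile: Profile, feats: ScaffoldFeatures,
               pred: FeaturePrediction,
               term_weights=(1.0, 1.0, 1.0, 1.0)) -> EnergyComponents:
    """Evaluate the four evolutionary terms for one sequence.

    All terms are per-residue normalized so sequence length never dominates
    the Z-scored totals; the torsion term averages over positions where the
    scaffold defines both angles.
    """
    seq_idx = encode_sequence(seq)
    if not (len(seq_idx) == profile.length == len(feats) == len(pred)):
        raise EnergyError(
            f"length mismatch: seq {len(seq_idx)}, profile {profile.length}, "
            f"features {len(feats)}, prediction {len(pred)}")
    arrays = (pred.ss_prob, pred.phi_pred, pred.psi_pred, pred.rsa_pred)
    prof_j, ss_j, ta_j, sa_j, defined = per_position_terms(
        seq_idx, profile, feats, arrays)
    length = len(seq_idx)
    n_def = max(1, int(defined.sum()))
    return EnergyComponents(
        e_profile=float(prof_j.sum() / length),
        e_ss=float(ss_j.sum() / length),
        e_ta=float(ta_j.sum() / n_def),
        e_sa=float(sa_j.sum() / length),
    )


def calibrate_baseline(energy_fn: Callable[[str], float], length: int,
                       n: int = 1000, seed: int = 0) -> EnergyBaseline:
    """Energy statistics of ``n`` uniform-random 20-letter sequences.

    Returns the sample mean and (n-1)-denominator standard deviation;
    deterministic for a fixed seed. Raises when the energy is degenerate
    (zero spread), which indicates a profile with no positional signal.
    """
    if n < 2:
        raise ValueError("baseline needs n >= 2")
    rng = np.random.default_rng(seed)
    energies = np.empty(n)
    for k in range(n):
        seq = decode_sequence(rng.integers(0, 20, size=length))
        energies[k] = energy_fn(seq)
    std = float(np.std(energies, ddof=1))
    if std <= 0.0 or not np.isfinite(std):
        raise EnergyError(
            "degenerate random-sequence baseline (zero energy spread); "
            "the profile carries no positional signal — use a richer "
            "homolog library")
    return EnergyBaseline(mean=float(np.mean(energies)), std=std, n=n,
                          seed=seed)


def z_score(components: EnergyComponents, base_evo: EnergyBaseline,
            base_phys: Optional[EnergyBaseline] = None, w: float = 0.0,
            term_weights=(1.0, 1.0, 1.0, 1.0)) -> float:
    """Z-scored design energy: (E - mean)/std for the evolutionary total,
    plus ``w`` times the independently Z-scored physics term when active.
    Lower is better; with w = -2.44 a physics energy *below* its random
    baseline (a good design) increases Z unless the sign convention of the
    physics scorer is chosen accordingly."""
    z = base_evo.z(components.total(term_weights))
    if w != 0.0:
        if components.e_phys is None or base_phys is None:
            raise EnergyError(
                "physics weight w is non-zero but no physics scorer / "
                "baseline is registered; attach a physics callback or set "
                "w = 0")
        z += w * base_phys.z(components.e_phys)
    return z
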
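"""Single-sequence predictors of local structure features.

During the sequence search every candidate mutation is scored by comparing
predicted secondary structure, torsion angles and relative solvent
accessibility of the decoy sequence against the scaffold's assigned
features, so prediction must cost O(L * window) per sequence and support
windowed incremental re-evaluation around a mutated position.

Two interchangeable predictor variants are provided:

* ``propensity`` — fixed per-residue H/E/C propensity scales and a
  hydropathy-derived exposure scale, averaged over a sliding window. No
  training required; this is the default design-time predictor.
* ``neural`` — small feedforward networks (one hidden layer) on one-hot
  sliding windows, trained on synthetic chains with structure-assigned
  labels. Deterministic for a fixed seed.

Torsion angles are not regressed directly: both variants convert SS class
probabilities into phi/psi via circular interpolation between canonical
class bin centers (helix -62/-41, sheet -120/135, coil -75/150).
"""
from __future__ import annotations

import dataclasses
import pickle
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.neural_network import MLPClassifier, MLPRegressor

from ._data import (
    N_AA,
    PHI_CENTERS,
    PSI_CENTERS,
    RSA_PROPENSITY,
    SS_CLASS_INDEX,
    SS_CLASSES,
    SS_PROPENSITY,
    encode_sequence,
)
from .structio import ScaffoldFeatures

MODEL_FORMAT_VERSION = 1


@dataclasses.dataclass
class FeaturePrediction:
    """Per-residue predicted features for one sequence."""

    ss_prob: np.ndarray  # (L, 3) over H/E/C, rows sum to 1
    phi_pred: np.ndarray  # degrees
    psi_pred: np.ndarray
    rsa_pred: np.ndarray  # [0, 1]

    @property
    def ss(self) -> str:
        return "".join(SS_CLASSES[i] for i in self.ss_prob.argmax(axis=1))

    def __len__(self) -> int:
        return len(self.rsa_pred)


def _check_window(window: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")


def torsions_from_ss_prob(ss_prob: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Circular-mean phi/psi from SS class probabilities and bin centers."""
    phi_rad = np.radians(PHI_CENTERS)
    psi_rad = np.radians(PSI_CENTERS)
    phi = np.degrees(np.arctan2(ss_prob @ np.sin(phi_rad),
                                ss_prob @ np.cos(phi_rad)))
    psi = np.degrees(np.arctan2(ss_prob @ np.sin(psi_rad),
                                ss_prob @ np.cos(psi_rad)))
    return phi, psi


class BasePredictor:
    """Interface shared by all predictor variants."""

    window: int
    variant: str

    def predict_arrays(self, seq_idx: np.ndarray):
        """(ss_prob (L,3), phi (L,), psi (L,), rsa (L,)) for an
        integer-encoded sequence."""
        raise NotImplementedError

    def predict_rows(self, seq_idx: np.ndarray, positions: np.ndarray):
        """Same as :meth:`predict_arrays` restricted to ``positions``.

        The default implementation predicts everything and slices; fast
        variants override this for the search engine's incremental path.
        """
        ss, phi, psi, rsa = self.predict_arrays(seq_idx)
        return ss[positions], phi[positions], psi[positions], rsa[positions]

    def predict(self, seq: str) -> FeaturePrediction:
        ss, phi, psi, rsa = self.predict_arrays(encode_sequence(seq))
        return FeaturePrediction(ss, phi, psi, rsa)


def _window_index(length: int, window: int) -> Tuple[np.ndarray, np.ndarray]:
    """(L, window) neighbour index matrix and validity mask; out-of-chain
    slots point at position 0 with mask False (edges use partial windows)."""
    hw = window // 2
    offsets = np.arange(-hw, hw + 1)
    idx = np.arange(length)[:, None] + offsets[None, :]
    mask = (idx >= 0) & (idx < length)
    return np.clip(idx, 0, length - 1), mask


class PropensityPredictor(BasePredictor):
    """Window-smoothed propensity-scale predictor (training-free)."""

    variant = "propensity"

    def __init__(self, window: int = 15):
        _check_window(window)
        self.window = window

    def predict_arrays(self, seq_idx: np.ndarray):
        seq_idx = np.asarray(seq_idx)
        idx, mask = _window_index(len(seq_idx), self.window)
        return self._from_windows(seq_idx, idx, mask)

    def predict_rows(self, seq_idx: np.ndarray, positions: np.ndarray):
        seq_idx = np.asarray(seq_idx)
        idx, mask = _window_index(len(seq_idx), self.window)
        return self._from_windows(seq_idx, idx[positions], mask[positions])

    def _from_windows(self, seq_idx, idx, mask):
        prop = SS_PROPENSITY[seq_idx[idx]] * mask[:, :, None]
        sums = prop.sum(axis=1)
        ss_prob = sums / sums.sum(axis=1, keepdims=True)
        rsa_vals = RSA_PROPENSITY[seq_idx[idx]] * mask
        rsa = np.clip(rsa_vals.sum(axis=1) / mask.sum(axis=1), 0.0, 1.0)
        phi, psi = torsions_from_ss_prob(ss_prob)
        return ss_prob, phi, psi, rsa


class NeuralPredictor(BasePredictor):
    """One-hidden-layer feedforward nets on one-hot sliding windows."""

    variant = "neural"

    def __init__(self, window: int, ss_net: MLPClassifier,
                 rsa_net: MLPRegressor, q3_holdout: float = float("nan")):
        _check_window(window)
        self.window = window
        self.ss_net = ss_net
        self.rsa_net = rsa_net
        self.q3_holdout = q3_holdout

    def _encode_windows(self, seq_idx, idx, mask):
        # 21 channels: 20 residues + 1 out-of-chain padding flag
        n, w = idx.shape
        feat = np.zeros((n, w, N_AA + 1))
        rows = np.repeat(np.arange(n), w)
        cols = np.tile(np.arange(w), n)
        chan = np.where(mask.ravel(), seq_idx[idx].ravel(), N_AA)
        feat[rows, cols, chan] = 1.0
        return feat.reshape(n, w * (N_AA + 1))

    def predict_arrays(self, seq_idx: np.ndarray):
        seq_idx = np.asarray(seq_idx)
        idx, mask = _window_index(len(seq_idx), self.window)
        return self._from_windows(seq_idx, idx, mask)

    def predict_rows(self, seq_idx, positions):
        seq_idx = np.asarray(seq_idx)
        idx, mask = _window_index(len(seq_idx), self.window)
        return self._from_windows(seq_idx, idx[positions], mask[positions])

    def _from_windows(self, seq_idx, idx, mask):
        x = self._encode_windows(seq_idx, idx, mask)
        raw = self.ss_net.predict_proba(x)
        ss_prob = np.zeros((len(x), 3))
        for k, cls in enumerate(self.ss_net.classes_):
            ss_prob[:, int(cls)] = raw[:, k]
        missing = 1.0 - ss_prob.sum(axis=1)
        ss_prob[:, SS_CLASS_INDEX["C"]] += np.maximum(missing, 0.0)
        ss_prob /= ss_prob.sum(axis=1, keepdims=True)
        rsa = np.clip(self.rsa_net.predict(x), 0.0, 1.0)
        phi, psi = torsions_from_ss_prob(ss_prob)
        return ss_prob, phi, psi, rsa


class ScaffoldEchoPredictor(BasePredictor):
    """Diagnostic predictor that always returns the scaffold's own features
    as one-hot SS probabilities — regardless of sequence. Makes the three
    feature-match energy terms identically zero, which isolates the profile
    term in tests of the search machinery."""

    variant = "echo"

    def __init__(self, feats: ScaffoldFeatures):
        self.window = 3
        self._ss_prob = np.zeros((len(feats), 3))
        for i, c in enumerate(feats.ss):
            self._ss_prob[i, SS_CLASS_INDEX[c]] = 1.0
        self._phi = np.nan_to_num(feats.phi, nan=0.0)
        self._psi = np.nan_to_num(feats.psi, nan=0.0)
        self._rsa = feats.rsa.copy()
        # overwrite torsions with the scaffold's so the match is exact
        self._phi = np.where(np.isnan(feats.phi), 0.0, feats.phi)
        self._psi = np.where(np.isnan(feats.psi), 0.0, feats.psi)

    def predict_arrays(self, seq_idx: np.ndarray):
        return self._ss_prob, self._phi, self._psi, self._rsa


def predict_features(seq: str, model: BasePredictor) -> FeaturePrediction:
    """Predict SS probabilities, phi/psi and relative SA for a sequence."""
    return model.predict(seq)


def train_predictor(
    training_set: Sequence[Tuple[str, ScaffoldFeatures]],
    window: int = 15,
    seed: int = 0,
    hidden: int = 32,
    holdout_fraction: float = 0.2,
) -> NeuralPredictor:
    """Train the neural predictor variant on (sequence, features) chains.

    Chains are split into train/held-out sets by order (the trailing
    ``holdout_fraction`` held out); the held-out 3-state SS accuracy is
    stored as ``q3_holdout``. Deterministic for fixed inputs and seed.
    """
    _check_window(window)
    if not training_set:
        raise ValueError("training set is empty")
    if len(training_set) < 10:
        raise ValueError("need at least 10 training chains")

    n_hold = max(1, int(round(holdout_fraction * len(training_set))))
    train = list(training_set[:-n_hold])
    hold = list(training_set[-n_hold:])

    scratch = NeuralPredictor.__new__(NeuralPredictor)
    scratch.window = window

    def encode_set(chains):
        xs, y_ss, y_rsa = [], [], []
        for seq, feats in chains:
            seq_idx = encode_sequence(seq)
            idx, mask = _window_index(len(seq_idx), window)
            xs.append(NeuralPredictor._encode_windows(scratch, seq_idx, idx, mask))
            y_ss.append([SS_CLASS_INDEX[c] for c in feats.ss])
            y_rsa.append(feats.rsa)
        return (np.vstack(xs), np.concatenate(y_ss).astype(int),
                np.concatenate(y_rsa))

    x_tr, ss_tr, rsa_tr = encode_set(train)
    x_ho, ss_ho, _ = encode_set(hold)

    ss_net = MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=400,
                           random_state=seed, alpha=1e-3)
    ss_net.fit(x_tr, ss_tr)
    rsa_net = MLPRegressor(hidden_layer_sizes=(hidden,), max_iter=400,
                           random_state=seed + 1, alpha=1e-3)
    rsa_net.fit(x_tr, rsa_tr)

    q3 = float(np.mean(ss_net.predict(x_ho) == ss_ho))
    return NeuralPredictor(window, ss_net, rsa_net, q3_holdout=q3)


def save_predictor(model: BasePredictor, path) -> None:
    bundle = {"format_version": MODEL_FORMAT_VERSION,
              "variant": model.variant, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(bundle, fh)


def load_predictor(path) -> BasePredictor:
    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    if bundle.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported predictor bundle version")
    return bundle["model"]
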
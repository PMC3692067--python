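"""Z-score-guided Metropolis Monte Carlo search over sequence space.

One sweep attempts L single-position substitutions (L = scaffold length):
a mutable position is picked uniformly, a different allowed residue is
proposed uniformly, and the move is accepted when the Z-score does not
increase or with probability exp(-dZ/T) otherwise. After each sweep the
current sequence is recorded as one decoy, so a trajectory of n sweeps
contributes n decoys and the pooled archive holds
n_traj * (n_sweeps - burn_in) sequences.

Design constraints are enforced structurally: frozen positions are never
proposed for mutation and excluded residues are never drawn, so every
recorded decoy satisfies them by construction.

The engine keeps per-position energy-term caches and re-evaluates only the
prediction window around a mutated position. For the propensity predictor
the window re-evaluation reduces to updating running propensity sums,
which is what makes full-size runs (10 x 30,000 sweeps) practical on one
processor.
"""
from __future__ import annotations

import dataclasses
import gzip
import math
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._data import (
    AA_ALPHABET,
    AA_INDEX,
    N_AA,
    PHI_CENTERS,
    PSI_CENTERS,
    RSA_PROPENSITY,
    SS_PROPENSITY,
    decode_sequence,
    encode_sequence,
)
from ._geom import wrapped_angle_diff
from .energy import (
    DesignConfig,
    EnergyBaseline,
    EnergyComponents,
    EnergyError,
    calibrate_baseline,
    scaffold_feature_arrays,
    z_score,
)
from .features import BasePredictor, PropensityPredictor
from .profile import Profile
from .structio import ScaffoldFeatures


class SearchError(ValueError):
    pass


@dataclasses.dataclass
class DesignConstraints:
    """Frozen positions and per-position excluded residues (0-based)."""

    frozen: Set[int] = dataclasses.field(default_factory=set)
    excluded: Dict[int, Set[str]] = dataclasses.field(default_factory=dict)

    def validate(self, length: int) -> None:
        for p in self.frozen:
            if not 0 <= p < length:
                raise ValueError(f"frozen position {p} outside 0..{length - 1}")
        for p, aas in self.excluded.items():
            if not 0 <= p < length:
                raise ValueError(f"excluded position {p} outside sequence")
            bad = set(aas) - set(AA_ALPHABET)
            if bad:
                raise ValueError(f"unknown excluded residues {sorted(bad)}")
            if len(set(aas)) >= N_AA:
                raise ValueError(
                    f"position {p} excludes all 20 amino acids")

    def allowed_indices(self, length: int) -> List[np.ndarray]:
        """Allowed residue codes per position (frozen handled separately)."""
        out = []
        for p in range(length):
            banned = {AA_INDEX[a] for a in self.excluded.get(p, ())}
            out.append(np.array(
                [i for i in range(N_AA) if i not in banned], dtype=np.int64))
        return out


@dataclasses.dataclass
class Trajectory:
    """One simulation trajectory: a decoy per sweep plus run metadata."""

    seq_idx: np.ndarray  # (n_sweeps, L) int8 residue codes
    z: np.ndarray  # (n_sweeps,)
    components: np.ndarray  # (n_sweeps, 4): profile, ss, ta, sa terms
    seed: int
    acceptance_rate: float

    @property
    def n_sweeps(self) -> int:
        return self.seq_idx.shape[0]

    def sequences(self) -> List[str]:
        return [decode_sequence(row) for row in self.seq_idx]


@dataclasses.dataclass
class DecoyPool:
    """Post-burn-in decoys pooled across trajectories."""

    seq_idx: np.ndarray  # (N, L) int8
    z: np.ndarray
    traj: np.ndarray
    sweep: np.ndarray

    def __len__(self) -> int:
        return self.seq_idx.shape[0]

    def sequence(self, i: int) -> str:
        return decode_sequence(self.seq_idx[i])


def metropolis_accept(delta_z: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """The Metropolis rule on Z-score differences: downhill or equal moves
    always pass; uphill moves pass with probability exp(-dZ/T)."""
    if delta_z <= 0.0:
        return True
    return rng.random() < math.exp(-delta_z / temperature)


def random_start(length: int, constraints: DesignConstraints,
                 scaffold_seq: str, rng: np.random.Generator) -> str:
    """Uniform random sequence respecting frozen and excluded sets."""
    constraints.validate(length)
    allowed = constraints.allowed_indices(length)
    out = []
    for p in range(length):
        if p in constraints.frozen:
            out.append(scaffold_seq[p])
        else:
            out.append(AA_ALPHABET[rng.choice(allowed[p])])
    return "".join(out)


class DesignEngine:
    """Incremental energy bookkeeping plus the Metropolis kernel.

    Z-scores are linear in the evolutionary energy, so move decisions only
    need the energy difference divided by the baseline spread; full
    components are reassembled from running per-term sums when a decoy is
    recorded.
    """

    def __init__(
        self,
        profile: Profile,
        feats: ScaffoldFeatures,
        predictor: BasePredictor,
        config: DesignConfig,
        scaffold_seq: str,
        constraints: Optional[DesignConstraints] = None,
        baseline: Optional[EnergyBaseline] = None,
        physics: Optional[Callable[[str], float]] = None,
        physics_baseline: Optional[EnergyBaseline] = None,
    ):
        config.validate()
        self.profile = profile
        self.feats = feats
        self.predictor = predictor
        self.config = config
        self.scaffold_seq = scaffold_seq
        self.constraints = constraints or DesignConstraints()
        self.length = profile.length
        self.constraints.validate(self.length)
        self.physics = physics
        self.physics_baseline = physics_baseline
        if config.w != 0.0 and physics is None:
            raise EnergyError(
                "physics weight w is non-zero but no physics scorer is "
                "registered")

        self.lo = profile.log_odds
        (self.ss_idx, self.phi_s, self.psi_s,
         self.defined, self.rsa_s) = scaffold_feature_arrays(feats)
        self.n_def = max(1, int(self.defined.sum()))
        self.tw = tuple(config.term_weights)

        self.allowed = self.constraints.allowed_indices(self.length)
        # with every position frozen the search degenerates to recording
        # the scaffold sequence each sweep (sweeps attempt nothing)
        self.mutable = np.array(
            [p for p in range(self.length) if p not in self.constraints.frozen],
            dtype=np.int64)
        # rank of each residue code within the allowed list of a position,
        # for O(1) "uniform over allowed minus current" draws
        self.rank = np.full((self.length, N_AA), -1, dtype=np.int64)
        for p in range(self.length):
            for r, a in enumerate(self.allowed[p]):
                self.rank[p, a] = r

        hw = predictor.window // 2
        self.win_lo = np.maximum(0, np.arange(self.length) - hw)
        self.win_hi = np.minimum(self.length, np.arange(self.length) + hw + 1)

        self._fast = isinstance(predictor, PropensityPredictor)
        if self._fast:
            self._phi_sin = np.sin(np.radians(PHI_CENTERS))
            self._phi_cos = np.cos(np.radians(PHI_CENTERS))
            self._psi_sin = np.sin(np.radians(PSI_CENTERS))
            self._psi_cos = np.cos(np.radians(PSI_CENTERS))
        from ._fastpath import HAVE_NUMBA, sweep_kernel
        self._compiled = self._fast and HAVE_NUMBA and physics is None
        if self._compiled:
            self._kernel = sweep_kernel
            self._phi_s0 = np.nan_to_num(self.phi_s)
            self._psi_s0 = np.nan_to_num(self.psi_s)
            self._allowed_off = np.zeros(self.length + 1, dtype=np.int64)
            for p in range(self.length):
                self._allowed_off[p + 1] = (self._allowed_off[p]
                                            + self.allowed[p].size)
            self._allowed_flat = np.concatenate(self.allowed)
            self._ss_scratch = np.empty(predictor.window)
            self._ta_scratch = np.empty(predictor.window)
            self._sa_scratch = np.empty(predictor.window)

        if baseline is None:
            baseline = calibrate_baseline(
                self.sequence_energy, self.length,
                n=config.n_baseline, seed=config.seed + 10_000)
        self.baseline = baseline

    # -- full evaluation ---------------------------------------------------

    def components_of(self, seq_idx: np.ndarray) -> EnergyComponents:
        from .energy import per_position_terms

        arrays = self.predictor.predict_rows(seq_idx, np.arange(self.length))
        prof_j, ss_j, ta_j, sa_j, _ = per_position_terms(
            seq_idx, self.profile, self.feats, arrays)
        comp = EnergyComponents(
            e_profile=float(prof_j.sum() / self.length),
            e_ss=float(ss_j.sum() / self.length),
            e_ta=float(ta_j.sum() / self.n_def),
            e_sa=float(sa_j.sum() / self.length),
        )
        if self.physics is not None:
            comp.e_phys = self.physics(decode_sequence(seq_idx))
        return comp

    def sequence_energy(self, seq: str) -> float:
        return self.components_of(encode_sequence(seq)).total(self.tw)

    def z_of(self, comp: EnergyComponents) -> float:
        return z_score(comp, self.baseline, self.physics_baseline,
                       self.config.w, self.tw)

    # -- incremental state -------------------------------------------------

    def _init_state(self, seq_idx: np.ndarray) -> None:
        from .energy import per_position_terms

        self.seq = seq_idx.astype(np.int64)
        arrays = self.predictor.predict_rows(self.seq, np.arange(self.length))
        prof_j, ss_j, ta_j, sa_j, _ = per_position_terms(
            self.seq, self.profile, self.feats, arrays)
        self.prof_j, self.ss_j, self.ta_j, self.sa_j = prof_j, ss_j, ta_j, sa_j
        if self._fast:
            w = self.predictor.window
            hw = w // 2
            prop = SS_PROPENSITY[self.seq]
            rprop = RSA_PROPENSITY[self.seq]
            self.ss_sum = np.zeros((self.length, 3))
            self.r_sum = np.zeros(self.length)
            self.win_n = (self.win_hi - self.win_lo).astype(float)
            for j in range(self.length):
                sl = slice(self.win_lo[j], self.win_hi[j])
                self.ss_sum[j] = prop[sl].sum(axis=0)
                self.r_sum[j] = rprop[sl].sum()
        if self.physics is not None:
            self.e_phys = self.physics(decode_sequence(self.seq))

    def _current_components(self) -> EnergyComponents:
        return EnergyComponents(
            e_profile=float(self.prof_j.sum() / self.length),
            e_ss=float(self.ss_j.sum() / self.length),
            e_ta=float(self.ta_j.sum() / self.n_def),
            e_sa=float(self.sa_j.sum() / self.length),
            e_phys=getattr(self, "e_phys", None),
        )

    def _propose_fast(self, p: int, new: int):
        """Delta terms for mutating position p under the propensity
        predictor, via window-sum updates."""
        old = self.seq[p]
        a, b = self.win_lo[p], self.win_hi[p]
        dv = SS_PROPENSITY[new] - SS_PROPENSITY[old]
        dr = RSA_PROPENSITY[new] - RSA_PROPENSITY[old]
        sl = slice(a, b)
        new_ss_sum = self.ss_sum[sl] + dv
        row_tot = new_ss_sum.sum(axis=1, keepdims=True)
        ssprob = new_ss_sum / row_tot
        rows = np.arange(a, b)
        ss_new = 1.0 - ssprob[rows - a, self.ss_idx[sl]]
        defined = self.defined[sl]
        phi_p = np.degrees(np.arctan2(ssprob @ self._phi_sin,
                                      ssprob @ self._phi_cos))
        psi_p = np.degrees(np.arctan2(ssprob @ self._psi_sin,
                                      ssprob @ self._psi_cos))
        dphi = wrapped_angle_diff(phi_p, np.where(defined, self.phi_s[sl], phi_p))
        dpsi = wrapped_angle_diff(psi_p, np.where(defined, self.psi_s[sl], psi_p))
        ta_new = np.where(defined, np.sqrt(dphi ** 2 + dpsi ** 2) / 180.0, 0.0)
        rsa_new = np.clip((self.r_sum[sl] + dr) / self.win_n[sl], 0.0, 1.0)
        sa_new = np.abs(rsa_new - self.rsa_s[sl])
        d_prof = self.lo[p, old] - self.lo[p, new]
        w1, w2, w3, w4 = self.tw
        delta_e = (w1 * d_prof / self.length
                   + w2 * (ss_new.sum() - self.ss_j[sl].sum()) / self.length
                   + w3 * (ta_new.sum() - self.ta_j[sl].sum()) / self.n_def
                   + w4 * (sa_new.sum() - self.sa_j[sl].sum()) / self.length)
        commit = (sl, ss_new, ta_new, sa_new, d_prof, dv, dr)
        return delta_e, commit

    def _propose_generic(self, p: int, new: int):
        from .energy import per_position_terms

        old = self.seq[p]
        hw = self.predictor.window // 2
        a, b = max(0, p - hw), min(self.length, p + hw + 1)
        sl = slice(a, b)
        self.seq[p] = new
        try:
            arrays = self.predictor.predict_rows(self.seq, np.arange(a, b))
            sub = self.seq[sl]
            ss_prob, phi_p, psi_p, rsa_p = arrays
            prof_row = -self.lo[np.arange(a, b), sub]
            ss_new = 1.0 - ss_prob[np.arange(b - a), self.ss_idx[sl]]
            defined = self.defined[sl]
            dphi = wrapped_angle_diff(
                phi_p, np.where(defined, self.phi_s[sl], phi_p))
            dpsi = wrapped_angle_diff(
                psi_p, np.where(defined, self.psi_s[sl], psi_p))
            ta_new = np.where(defined,
                              np.sqrt(dphi ** 2 + dpsi ** 2) / 180.0, 0.0)
            sa_new = np.abs(rsa_p - self.rsa_s[sl])
            new_phys = self.physics(decode_sequence(self.seq)) \
                if self.physics is not None else None
        finally:
            self.seq[p] = old
        d_prof = self.lo[p, old] - self.lo[p, new]
        w1, w2, w3, w4 = self.tw
        delta_e = (w1 * d_prof / self.length
                   + w2 * (ss_new.sum() - self.ss_j[sl].sum()) / self.length
                   + w3 * (ta_new.sum() - self.ta_j[sl].sum()) / self.n_def
                   + w4 * (sa_new.sum() - self.sa_j[sl].sum()) / self.length)
        commit = (sl, ss_new, ta_new, sa_new, d_prof, None, None, new_phys)
        return delta_e, commit

    def _commit(self, p: int, new: int, commit) -> None:
        if self._fast:
            sl, ss_new, ta_new, sa_new, d_prof, dv, dr = commit
            self.ss_sum[sl] += dv
            self.r_sum[sl] += dr
        else:
            sl, ss_new, ta_new, sa_new, d_prof, _, _, new_phys = commit
            if new_phys is not None:
                self.e_phys = new_phys
        self.ss_j[sl] = ss_new
        self.ta_j[sl] = ta_new
        self.sa_j[sl] = sa_new
        self.prof_j[p] += d_prof
        self.seq[p] = new

    # -- the Metropolis kernel --------------------------------------------

    def sweep(self, rng: np.random.Generator) -> Tuple[int, int]:
        """L attempted single-position substitutions; returns
        (accepted, attempted)."""
        length = self.length
        n_mut = self.mutable.size
        if n_mut == 0:
            return 0, 0
        pos_draw = rng.integers(0, n_mut, size=length)
        unif = rng.random(size=length)
        accept_unif = rng.random(size=length)
        if self._compiled:
            w1, w2, w3, w4 = self.tw
            accepted = self._kernel(
                self.seq, self.ss_sum, self.r_sum,
                self.prof_j, self.ss_j, self.ta_j, self.sa_j,
                self.lo, SS_PROPENSITY, RSA_PROPENSITY,
                self.ss_idx, self._phi_s0, self._psi_s0,
                self.defined, self.rsa_s,
                self.win_lo, self.win_hi, self.win_n,
                self.mutable, self._allowed_flat, self._allowed_off,
                self.rank, pos_draw, unif, accept_unif,
                float(self.n_def), w1, w2, w3, w4,
                1.0 / self.baseline.std, 1.0 / self.config.temperature,
                self._phi_sin, self._phi_cos, self._psi_sin, self._psi_cos,
                self._ss_scratch, self._ta_scratch, self._sa_scratch,
            )
            return int(accepted), length
        accepted = 0
        propose = self._propose_fast if self._fast else self._propose_generic
        inv_t = 1.0 / self.config.temperature
        inv_std = 1.0 / self.baseline.std
        phys_scale = (self.config.w / self.physics_baseline.std
                      if (self.physics is not None and
                          self.physics_baseline is not None) else 0.0)
        for k in range(length):
            p = self.mutable[pos_draw[k]]
            al = self.allowed[p]
            n_al = al.size
            if n_al < 2:
                continue
            cur_rank = self.rank[p, self.seq[p]]
            r = int(unif[k] * (n_al - 1))
            if r >= cur_rank >= 0:
                r += 1
            new = al[r]
            delta_e, commit = propose(p, new)
            delta_z = delta_e * inv_std
            if phys_scale != 0.0:
                delta_z += phys_scale * (commit[7] - self.e_phys)
            if delta_z <= 0.0 or accept_unif[k] < math.exp(-delta_z * inv_t):
                self._commit(p, new, commit)
                accepted += 1
        return accepted, length

    def run_trajectory(self, rng: np.random.Generator,
                       seed_label: int = 0) -> Trajectory:
        cfg = self.config
        start = random_start(self.length, self.constraints,
                             self.scaffold_seq, rng)
        self._init_state(encode_sequence(start))
        n = cfg.n_sweeps
        seqs = np.empty((n, self.length), dtype=np.int8)
        zs = np.empty(n)
        comps = np.empty((n, 4))
        n_accepted = 0
        n_attempted = 0
        for s in range(n):
            acc, att = self.sweep(rng)
            n_accepted += acc
            n_attempted += att
            comp = self._current_components()
            seqs[s] = self.seq
            zs[s] = self.z_of(comp)
            comps[s] = (comp.e_profile, comp.e_ss, comp.e_ta, comp.e_sa)
        return Trajectory(
            seq_idx=seqs, z=zs, components=comps, seed=seed_label,
            acceptance_rate=n_accepted / max(1, n_attempted))


def trajectory_rng(seed: int, traj_index: int) -> np.random.Generator:
    """Per-trajectory generator derived deterministically from the job seed
    so serial and parallel execution agree."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(traj_index,))
    return np.random.Generator(np.random.PCG64(ss))


def run_design(
    profile: Profile,
    feats: ScaffoldFeatures,
    predictor: BasePredictor,
    config: DesignConfig,
    scaffold_seq: str,
    constraints: Optional[DesignConstraints] = None,
    baseline: Optional[EnergyBaseline] = None,
    physics: Optional[Callable[[str], float]] = None,
    physics_baseline: Optional[EnergyBaseline] = None,
) -> List[Trajectory]:
    """Run ``config.n_traj`` independent trajectories from random starts.

    Each trajectory draws its generator from (config.seed, trajectory
    index), so results are bit-identical regardless of execution order.
    """
    engine = DesignEngine(profile, feats, predictor, config, scaffold_seq,
                          constraints, baseline, physics, physics_baseline)
    out = []
    for t in range(config.n_traj):
        rng = trajectory_rng(config.seed, t)
        out.append(engine.run_trajectory(rng, seed_label=t))
    return out


def pool_decoys(trajectories: Sequence[Trajectory],
                burn_in: int) -> DecoyPool:
    """Concatenate per-trajectory decoys from sweep ``burn_in`` onward."""
    if trajectories and burn_in >= trajectories[0].n_sweeps:
        raise ValueError("burn_in must be smaller than n_sweeps")
    seqs, zs, tr, sw = [], [], [], []
    for t_i, traj in enumerate(trajectories):
        n = traj.n_sweeps
        seqs.append(traj.seq_idx[burn_in:])
        zs.append(traj.z[burn_in:])
        tr.append(np.full(n - burn_in, t_i))
        sw.append(np.arange(burn_in, n))
    return DecoyPool(
        seq_idx=np.vstack(seqs),
        z=np.concatenate(zs),
        traj=np.concatenate(tr),
        sweep=np.concatenate(sw),
    )


def write_decoy_archive(pool: DecoyPool, path) -> None:
    """Gzip tab-separated decoy archive: trajectory, sweep, Z, sequence."""
    with gzip.open(path, "wt") as fh:
        fh.write("traj\tsweep\tz\tsequence\n")
        for i in range(len(pool)):
            fh.write(f"{pool.traj[i]}\t{pool.sweep[i]}\t{pool.z[i]:.6f}\t"
                     f"{pool.sequence(i)}\n")


def read_decoy_archive(path) -> DecoyPool:
    with gzip.open(path, "rt") as fh:
        header = fh.readline()
        tr, sw, zs, seqs = [], [], [], []
        for line in fh:
            t, s, z, seq = line.rstrip("\n").split("\t")
            tr.append(int(t))
            sw.append(int(s))
            zs.append(float(z))
            seqs.append(encode_sequence(seq).astype(np.int8))
    return DecoyPool(seq_idx=np.array(seqs), z=np.array(zs),
                     traj=np.array(tr), sweep=np.array(sw))
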
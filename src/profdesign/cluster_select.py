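"""Decoy clustering, seed-design extraction and design quality reports.

Decoys are clustered under a BLOSUM62-derived sequence distance with the
threshold-expansion rule: starting from zero the distance threshold grows
in fixed steps until the largest neighbour ball (the primary cluster)
holds at least the requested fraction (default 40%) of the pooled
sequences; that cluster is removed and the procedure repeats at the same
threshold for up to ten clusters. The representative ("seed") of each
cluster is its lowest-Z member, ties broken on (Z, sequence) so pool order
never matters. Reports carry sequence identity to the scaffold, the
confidence score (the seed's Z; lower = more confident), per-feature
normalized relative errors and binding-site conservation.

The normalized relative error of a feature is NRE = (EDS - ETS)/ETS where
EDS is the predictor's error on the design sequence against the scaffold's
assigned features and ETS the same error for the scaffold's own sequence;
negative NRE means the design sequence is predicted to fit the scaffold
structure better than the native sequence does.
"""
from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._data import AA_INDEX, BLOSUM62, N_AA, decode_sequence, encode_sequence
from ._geom import wrapped_angle_diff
from .features import BasePredictor
from .mcsearch import DecoyPool
from .structio import ScaffoldFeatures, Structure, binding_site_residues


class ClusterError(ValueError):
    pass


@dataclasses.dataclass
class DecoyCluster:
    members: np.ndarray  # decoy indices into the (sub)pool
    seed_index: int  # pool index of the lowest-Z member
    threshold_at_stop: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class DesignReport:
    rank: int
    design_score: float  # seed Z; lower = more confident
    identity_pct: float
    nre_ss: Optional[float]
    nre_sa: Optional[float]
    nre_phi: Optional[float]
    nre_psi: Optional[float]
    binding_site_conserved: Dict[int, bool]
    sequence: str
    cluster_size: int


# ---------------------------------------------------------------------------
# BLOSUM62 sequence distance
# ---------------------------------------------------------------------------

# Pre-derived per-pair distance table: d1(a,b) = (B(a,a)+B(b,b)-2B(a,b))/2,
# the standard score-to-distance transform (symmetric, zero on identity).
_PAIR_DIST = (np.diag(BLOSUM62)[:, None] + np.diag(BLOSUM62)[None, :]
              - 2.0 * BLOSUM62) / 2.0


def seq_distance(a: str, b: str) -> float:
    """Length-normalized BLOSUM62 distance between equal-length sequences."""
    if len(a) != len(b):
        raise ClusterError(f"length mismatch: {len(a)} vs {len(b)}")
    ia, ib = encode_sequence(a), encode_sequence(b)
    return float(_PAIR_DIST[ia, ib].mean())


def pairwise_distances(seq_idx: np.ndarray) -> np.ndarray:
    """All-pairs BLOSUM62 distances for an (n, L) integer sequence array.

    Averages the pre-derived 20x20 per-pair distance table over positions;
    a compiled kernel walks the pair triangle directly, with a dense
    matmul over one-hot encodings as fallback when numba is unavailable.
    """
    from ._fastpath import HAVE_NUMBA, pair_distance_kernel

    n, length = seq_idx.shape
    if HAVE_NUMBA:
        return pair_distance_kernel(
            np.ascontiguousarray(seq_idx, dtype=np.int8),
            _PAIR_DIST.astype(np.float32))
    onehot = np.zeros((n, length * N_AA), dtype=np.float32)
    flat = np.arange(length) * N_AA + seq_idx
    rows = np.repeat(np.arange(n), length)
    onehot[rows, flat.ravel()] = 1.0
    scored = BLOSUM62.astype(np.float32)[seq_idx]  # (n, L, 20)
    cross = scored.reshape(n, length * N_AA) @ onehot.T  # S_ab
    self_scores = np.diag(BLOSUM62).astype(np.float32)[seq_idx].sum(axis=1)
    d = (self_scores[:, None] + self_scores[None, :] - 2.0 * cross) / (2.0 * length)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


# ---------------------------------------------------------------------------
# Threshold-expansion clustering
# ---------------------------------------------------------------------------

def cluster_decoys(
    pool: DecoyPool,
    cluster_frac: float = 0.4,
    step: float = 0.25,
    max_clusters: int = 10,
    subsample: Optional[int] = 20000,
    seed: int = 0,
) -> Tuple[List[DecoyCluster], np.ndarray]:
    """Cluster a decoy pool; returns (clusters, subsample_indices).

    When the pool exceeds ``subsample`` decoys a seeded uniform subsample
    is clustered instead (the all-pairs distance matrix is quadratic); the
    expansion stop criterion applies to the subsample. Cluster member
    indices refer to the full pool via the returned index array.
    """
    n_total = len(pool)
    if n_total == 0:
        raise ClusterError("empty decoy pool")
    if not 0.0 < cluster_frac < 1.0:
        raise ClusterError("cluster_frac must be in (0, 1)")
    if subsample is not None and n_total > subsample:
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(n_total, size=subsample, replace=False))
    else:
        indices = np.arange(n_total)
    seq_idx = pool.seq_idx[indices].astype(np.int64)
    z = pool.z[indices]
    n = len(indices)

    dist = pairwise_distances(seq_idx)

    # expand the threshold until the biggest neighbour ball is big enough
    threshold = 0.0
    target = cluster_frac * n
    eps = 1e-9
    while True:
        within = dist <= threshold + eps
        counts = within.sum(axis=1)
        if counts.max() >= target or threshold > dist.max():
            break
        threshold += step

    clusters: List[DecoyCluster] = []
    alive = np.ones(n, dtype=bool)
    while alive.any() and len(clusters) < max_clusters:
        within = (dist <= threshold + eps) & alive[None, :] & alive[:, None]
        counts = within.sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # ties: lowest index wins
        members_local = np.where(within[center])[0]
        member_pool_idx = indices[members_local]
        # representative: lowest Z, ties broken on the sequence codes
        zs = z[members_local]
        sub = seq_idx[members_local]
        order = np.lexsort(tuple(sub.T[::-1]) + (zs,))
        seed_idx = int(member_pool_idx[order[0]])
        clusters.append(DecoyCluster(
            members=member_pool_idx,
            seed_index=seed_idx,
            threshold_at_stop=threshold,
        ))
        alive[members_local] = False
    return clusters, indices


# ---------------------------------------------------------------------------
# NRE and report assembly
# ---------------------------------------------------------------------------

def _prediction_errors(seq: str, feats: ScaffoldFeatures,
                       predictor: BasePredictor):
    """(ss_error, sa_error, phi_error, psi_error) of the predictor on one
    sequence against the scaffold's assigned features: 3-state error rate,
    mean |dRSA|, and mean wrapped |dphi|, |dpsi| in degrees."""
    pred = predictor.predict(seq)
    ss_err = float(np.mean([p != s for p, s in zip(pred.ss, feats.ss)]))
    sa_err = float(np.mean(np.abs(pred.rsa_pred - feats.rsa)))
    phi_def = np.isfinite(feats.phi)
    psi_def = np.isfinite(feats.psi)
    phi_err = float(np.mean(wrapped_angle_diff(
        pred.phi_pred[phi_def], feats.phi[phi_def])))
    psi_err = float(np.mean(wrapped_angle_diff(
        pred.psi_pred[psi_def], feats.psi[psi_def])))
    return ss_err, sa_err, phi_err, psi_err


def compute_nre(design_seq: str, scaffold_seq: str,
                feats: ScaffoldFeatures, predictor: BasePredictor
                ) -> Tuple[Optional[float], Optional[float],
                           Optional[float], Optional[float]]:
    """Normalized relative errors (SS, SA, phi, psi) of a design sequence.

    NRE = (EDS - ETS)/ETS per feature; a feature whose scaffold-sequence
    error ETS is zero has an undefined NRE, reported as None rather than
    infinity.
    """
    if len(design_seq) != len(scaffold_seq):
        raise ClusterError("design and scaffold sequences differ in length")
    eds = _prediction_errors(design_seq, feats, predictor)
    ets = _prediction_errors(scaffold_seq, feats, predictor)
    out = []
    for e_d, e_t in zip(eds, ets):
        out.append(None if e_t == 0.0 else (e_d - e_t) / e_t)
    return tuple(out)


def sequence_identity_pct(a: str, b: str) -> float:
    return 100.0 * float(np.mean([x == y for x, y in zip(a, b)]))


def select_designs(
    clusters: Sequence[DecoyCluster],
    pool: DecoyPool,
    scaffold_seq: str,
    feats: Optional[ScaffoldFeatures] = None,
    predictor: Optional[BasePredictor] = None,
    scaffold: Optional[Structure] = None,
    binding_radius: float = 8.0,
    max_designs: int = 10,
) -> List[DesignReport]:
    """Reports for up to ``max_designs`` cluster seeds, ordered by
    decreasing cluster size. NRE columns are filled when the scaffold
    features and a predictor are supplied; binding-site conservation when
    the scaffold structure carries hetero atoms."""
    if not clusters:
        raise ClusterError("no clusters to select designs from")
    ranked = sorted(clusters, key=lambda c: -c.size)[:max_designs]
    site: List[int] = []
    site_pos: Dict[int, int] = {}
    if scaffold is not None and scaffold.hetero_atoms:
        numbers = binding_site_residues(scaffold, binding_radius)
        for pos, res in enumerate(scaffold.residues):
            if res.number in numbers:
                site_pos[res.number] = pos
    reports = []
    for rank, cluster in enumerate(ranked, start=1):
        seq = pool.sequence(cluster.seed_index)
        if feats is not None and predictor is not None:
            nre = compute_nre(seq, scaffold_seq, feats, predictor)
        else:
            nre = (None, None, None, None)
        conserved = {num: seq[pos] == scaffold_seq[pos]
                     for num, pos in site_pos.items()}
        reports.append(DesignReport(
            rank=rank,
            design_score=float(pool.z[cluster.seed_index]),
            identity_pct=sequence_identity_pct(seq, scaffold_seq),
            nre_ss=nre[0], nre_sa=nre[1], nre_phi=nre[2], nre_psi=nre[3],
            binding_site_conserved=conserved,
            sequence=seq,
            cluster_size=cluster.size,
        ))
    return reports


# ---------------------------------------------------------------------------
# Output rendering
# ---------------------------------------------------------------------------

def render_report_text(report: DesignReport, scaffold_seq: str,
                       feats: ScaffoldFeatures,
                       scaffold: Optional[Structure] = None) -> str:
    """Human-readable per-design block: binding-site positions (when hetero
    atoms exist), the SS assignment line, scaffold sequence, identity marks
    and the design sequence."""
    lines = [f"# design rank {report.rank}  score {report.design_score:.3f}  "
             f"identity {report.identity_pct:.1f}%  "
             f"cluster_size {report.cluster_size}"]
    if report.binding_site_conserved:
        marks = " ".join(
            f"{num}{'+' if ok else '-'}"
            for num, ok in sorted(report.binding_site_conserved.items()))
        lines.append(f"binding-site residues (+conserved/-mutated): {marks}")
    lines.append("SS       " + feats.ss)
    lines.append("scaffold " + scaffold_seq)
    lines.append("         " + "".join(
        "|" if a == b else " " for a, b in zip(scaffold_seq, report.sequence)))
    lines.append("design   " + report.sequence)
    nre_bits = []
    for name, v in (("SS", report.nre_ss), ("SA", report.nre_sa),
                    ("phi", report.nre_phi), ("psi", report.nre_psi)):
        nre_bits.append(f"NRE_{name}=" + ("undef" if v is None else f"{v:+.3f}"))
    lines.append("  ".join(nre_bits))
    return "\n".join(lines) + "\n"


def write_designs_fasta(reports: Sequence[DesignReport], path) -> None:
    with open(path, "w") as fh:
        for r in reports:
            fh.write(f">design_{r.rank} score={r.design_score:.3f} "
                     f"identity={r.identity_pct:.1f}% "
                     f"cluster_size={r.cluster_size}\n{r.sequence}\n")


def summary_table(reports: Sequence[DesignReport]):
    """Per-design summary of identity and NRE columns as a DataFrame."""
    import pandas as pd

    rows = []
    for r in reports:
        rows.append({
            "rank": r.rank,
            "score": r.design_score,
            "identity_pct": r.identity_pct,
            "nre_ss": r.nre_ss,
            "nre_sa": r.nre_sa,
            "nre_phi": r.nre_phi,
            "nre_psi": r.nre_psi,
            "cluster_size": r.cluster_size,
            "sequence": r.sequence,
        })
    return pd.DataFrame(rows)
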
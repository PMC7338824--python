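"""Intra- and inter-site tumor heterogeneity (IISTH) summaries.

After voxel clustering, each tumor site s is described by its cluster
composition p_s = (p_{s,1}, ..., p_{s,K}) (fractions of the site's voxels in
each texture sub-region).  With w_s the site's fraction of all tumor voxels
and V_s its volume in mL, the per-patient summaries are

    cluSE   = -sum_{s,k} q_{s,k} log2 q_{s,k},  q_{s,k} = w_s * p_{s,k}
              (joint site-by-cluster entropy, bits; at most log2(S*K))
    cluSD   = population SD over clusters of the total cluster volume
              sum_s V_s * p_{s,k}  (mL)
    cluDiss = sum_{s<t} sqrt(V_s * V_t) * ||p_s - p_t||_2
              (volume-weighted pairwise divergence of cluster compositions;
              0 when all sites share the same composition or S = 1)

The higher the metrics, the more the texture sub-region make-up differs
between sites.  These functional forms are this package's committed
definitions, kept behind this single interface so alternatives can be
swapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cluster import ClusterAssignment, kernel_kmeans
from .datatypes import PipelineConfig, SegmentedVolume
from .errors import ParameterError
from .texture import TextureMap, TextureParams, texture_map

logger = logging.getLogger("radioprot")


@dataclass
class IISTHMetrics:
    """Per-patient heterogeneity triple plus the (S, K) it was computed at."""

    cluSE: float
    cluSD: float
    cluDiss: float
    S: int
    K: int

    def as_dict(self) -> dict:
        return {"cluSE": self.cluSE, "cluSD": self.cluSD, "cluDiss": self.cluDiss,
                "S": self.S, "K": self.K}


def iisth_from_proportions(p: np.ndarray, site_volumes_ml: np.ndarray,
                           site_weights: np.ndarray | None = None) -> IISTHMetrics:
    """IISTH metrics from an (S, K) site-composition matrix directly.

    ``p`` rows must each sum to 1; ``site_weights`` defaults to volumes
    normalized to 1.  Exposed separately so the closed-form fixtures in the
    tests can bypass clustering.
    """
    p = np.asarray(p, dtype=float)
    V = np.asarray(site_volumes_ml, dtype=float)
    S, K = p.shape
    if V.shape != (S,):
        raise ParameterError("site_volumes_ml must have one entry per site")
    if not np.allclose(p.sum(axis=1), 1.0):
        raise ParameterError("each site's cluster proportions must sum to 1")
    w = V / V.sum() if site_weights is None else np.asarray(site_weights, dtype=float)

    q = w[:, None] * p
    qpos = q[q > 0]
    cluSE = float(-(qpos * np.log2(qpos)).sum())

    cluster_vol = p.T @ V  # (K,) total volume of each cluster, mL
    cluSD = float(np.std(cluster_vol))  # ddof=0: one cluster -> 0

    cluDiss = 0.0
    for s in range(S):
        for t in range(s + 1, S):
            cluDiss += float(np.sqrt(V[s] * V[t]) * np.linalg.norm(p[s] - p[t]))

    if K == 1:
        logger.warning("degenerate single-cluster assignment: cluSD = cluDiss = 0")
    return IISTHMetrics(cluSE=cluSE, cluSD=cluSD, cluDiss=cluDiss, S=S, K=K)


def iisth(assignment: ClusterAssignment, volume: SegmentedVolume) -> IISTHMetrics:
    """IISTH metrics of one patient from a voxel cluster assignment.

    Site weights and volumes come from the full segmentation mask; cluster
    compositions come from the clustered voxels of each site.  Sites with no
    clustered voxel (degenerate tiny sites) are dropped from the summary with
    a warning.
    """
    S = volume.n_sites
    table = assignment.site_cluster_table(S).astype(float)  # (S, K)
    counts = np.bincount(volume.mask.ravel(), minlength=S + 1)[1:].astype(float)
    V = volume.site_volumes_ml()

    covered = table.sum(axis=1) > 0
    if not covered.all():
        logger.warning("%d site(s) have no clustered voxels; dropped from IISTH",
                       int((~covered).sum()))
        table, counts, V = table[covered], counts[covered], V[covered]
    p = table / table.sum(axis=1, keepdims=True)
    w = counts / counts.sum()
    m = iisth_from_proportions(p, V, site_weights=w)
    return IISTHMetrics(cluSE=m.cluSE, cluSD=m.cluSD, cluDiss=m.cluDiss,
                        S=int(covered.sum()), K=assignment.K)


def compute_iisth(volume: SegmentedVolume, params: TextureParams | None = None,
                  K: int = 4, kernel: str = "rbf", seed: int = 0, restarts: int = 5
                  ) -> tuple[IISTHMetrics, ClusterAssignment, TextureMap]:
    """Full texture stage for one patient: quantize -> texture map -> cluster -> IISTH.

    Voxels whose features could not be defined or imputed (sites of < 2
    voxels) are excluded from clustering but their sites still contribute
    volume if any of their voxels were clustered.
    """
    tmap = texture_map(volume, params)
    finite = tmap.finite_rows()
    if not finite.any():
        raise ParameterError("no voxel has defined texture features")
    assignment = kernel_kmeans(tmap.features[finite], K=K, kernel=kernel, seed=seed,
                               restarts=restarts, sites=tmap.sites[finite])
    metrics = iisth(assignment, volume)
    return metrics, assignment, tmap


def config_from(config: PipelineConfig) -> tuple[TextureParams, dict]:
    """Split a PipelineConfig into TextureParams and clustering kwargs."""
    t = config.texture
    params = TextureParams(
        n_levels=int(t["n_levels"]), window_radius=int(t["window_radius"]),
        offsets=tuple(tuple(o) for o in t["offsets"]),
        planar=bool(t["planar"]), symmetric=bool(t["symmetric"]),
    )
    c = config.clustering
    kwargs = {"K": int(c["n_clusters"]), "kernel": c["kernel"],
              "restarts": int(c["restarts"])}
    return params, kwargs
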
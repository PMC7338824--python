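"""Synthetic inputs with known ground truth.

Three generators emulate the pipeline's real-world inputs:

* :func:`generate_phantom` — multi-site CT phantoms: connected voxel blobs on
  a constant background, each filled with a smoothed Gaussian random field.
  A single ``heterogeneity`` knob in [0, 1] spreads the per-site smoothing
  scale and contrast amplitude apart (log-linearly), which directly moves the
  GLCM contrast/homogeneity of each site and hence the inter-site
  heterogeneity metrics.  At heterogeneity 0 every site is drawn from
  identical texture parameters.
* :func:`generate_omics` — a gene x site transcript matrix with planted
  low-CV ("conserved") genes, plus patient-matched transcript and protein
  matrices with planted transcript-protein correlation (Gaussian copula).
* :func:`generate_traits` — a radiologist-style trait table with planted
  protein-trait effects (logistic link for binary traits, log link for
  counts, latent-threshold for ordinal, linear for lengths) and two synthetic
  readers derived from the consolidated truth by symmetric label flips /
  additive noise.

Everything is deterministic given the seed (numpy PCG64 generators, fixed
draw order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .datatypes import OmicsMatrix, SegmentedVolume, TraitSpec, TraitTable, READERS
from .errors import ParameterError, SchemaError

logger = logging.getLogger("radioprot")


# ---------------------------------------------------------------------------
# phantoms

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one multi-site phantom volume.

    ``heterogeneity`` = 0 draws every site from identical texture parameters;
    larger values spread the per-site log smoothing scale and log contrast
    amplitude linearly apart (see :func:`site_texture_params` and
    :func:`parameter_divergence`).
    """

    n_sites: int = 3
    voxels_per_site: tuple[int, int] = (120, 260)
    heterogeneity: float = 0.5
    shape: tuple[int, int, int] = (48, 48, 6)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    background_hu: float = -50.0
    mean_hu: float = 40.0
    base_sigma: float = 1.3
    base_amplitude: float = 60.0
    sigma_log_spread: float = 0.9
    amplitude_log_spread: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")
        lo, hi = self.voxels_per_site
        if lo < 8 or hi < lo:
            raise ParameterError(
                f"voxels_per_site {self.voxels_per_site} too small for a connected blob")
        if not (0 <= self.heterogeneity <= 1):
            raise ParameterError("heterogeneity must lie in [0, 1]")


def site_texture_params(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (smoothing sigma, contrast amplitude) arrays.

    log sigma_s = log base_sigma + h * sigma_log_spread * delta_s with deltas
    evenly spaced in [-1, 1] (and reversed for the amplitudes, so the two
    knobs decouple across sites).
    """
    S = spec.n_sites
    deltas = np.linspace(-1.0, 1.0, S) if S > 1 else np.zeros(1)
    h = spec.heterogeneity
    sigma = spec.base_sigma * np.exp(h * spec.sigma_log_spread * deltas)
    amp = spec.base_amplitude * np.exp(h * spec.amplitude_log_spread * deltas[::-1])
    return sigma, amp


def parameter_divergence(spec: PhantomSpec) -> float:
    """Declared divergence functional of the site parameter sets.

    Variance of per-site log parameters, summed over the two parameters;
    equals h^2 * (spread^2_sigma + spread^2_amp) * var(deltas), strictly
    increasing in heterogeneity for S >= 2.
    """
    sigma, amp = site_texture_params(spec)
    return float(np.var(np.log(sigma)) + np.var(np.log(amp)))


_NEIGHBORS6 = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def _grow_blob(free: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray | None:
    """Grow one connected 6-connected blob of ~target voxels inside ``free``."""
    shape = free.shape
    free_idx = np.argwhere(free)
    if free_idx.size == 0:
        return None
    seed = free_idx[rng.integers(len(free_idx))]
    blob = np.zeros(shape, dtype=bool)
    blob[tuple(seed)] = True
    frontier = [tuple(seed + d) for d in _NEIGHBORS6]
    count = 1
    while count < target and frontier:
        i = rng.integers(len(frontier))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        v = frontier.pop()
        if not all(0 <= v[a] < shape[a] for a in range(3)):
            continue
        if blob[v] or not free[v]:
            continue
        blob[v] = True
        count += 1
        for d in _NEIGHBORS6:
            frontier.append((v[0] + d[0], v[1] + d[1], v[2] + d[2]))
    return blob if count >= min(8, target) else None


def generate_phantom(spec: PhantomSpec) -> SegmentedVolume:
    """Deterministic multi-site phantom volume for one synthetic patient.

    Each site is a connected blob; intensities within a site are a smoothed,
    unit-variance Gaussian random field scaled by the site's contrast
    amplitude around a common mean HU.  Background is constant.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    mask = np.zeros(shape, dtype=np.int32)
    blocked = np.zeros(shape, dtype=bool)
    # keep a 1-voxel in-plane margin off the grid border
    border = np.zeros(shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True

    for s in range(1, spec.n_sites + 1):
        target = int(rng.integers(spec.voxels_per_site[0], spec.voxels_per_site[1] + 1))
        blob = None
        for _attempt in range(10):
            blob = _grow_blob(~(blocked | border), target, rng)
            if blob is not None:
                break
        if blob is None:
            raise ParameterError(
                f"could not place connected site {s} of ~{target} voxels in grid {shape}")
        mask[blob] = s
        # block this site and a 1-voxel shell around it for later sites
        dil = blob.copy()
        for d in _NEIGHBORS6:
            dil |= np.roll(blob, shift=tuple(d), axis=(0, 1, 2))
        blocked |= dil

    sigma, amp = site_texture_params(spec)
    sigma_z_ratio = spec.spacing[0] / spec.spacing[2]
    intens = np.full(shape, spec.background_hu, dtype=float)
    for s in range(1, spec.n_sites + 1):
        field = rng.standard_normal(shape)
        field = gaussian_filter(field, sigma=(sigma[s - 1], sigma[s - 1],
                                              max(sigma[s - 1] * sigma_z_ratio, 1e-6)))
        sel = mask == s
        sd = field[sel].std()
        if sd > 0:
            field = field / sd
        intens[sel] = spec.mean_hu + amp[s - 1] * field[sel]
    return SegmentedVolume(intensities=intens, spacing=spec.spacing, mask=mask,
                           patient_id=f"phantom_seed{spec.seed}")


# ---------------------------------------------------------------------------
# omics

@dataclass(frozen=True)
class OmicsTruth:
    """Planted structure of the synthetic omics matrices.

    conserved_genes get a between-site CV from the low regime (|N(cv_low,
    cv_low_sd)|), all others from the high regime (lognormal around cv_high).
    correlated_genes get transcript-protein correlation rho_high (Gaussian
    copula), all others rho_null.
    """

    conserved_genes: tuple = ()
    correlated_genes: tuple = ()
    cv_low: float = 0.05
    cv_low_sd: float = 0.01
    cv_high: float = 0.5
    cv_high_log_sd: float = 0.35
    rho_high: float = 0.8
    rho_null: float = 0.0
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "conserved_genes": list(self.conserved_genes),
            "correlated_genes": list(self.correlated_genes),
            "cv_low": self.cv_low, "cv_low_sd": self.cv_low_sd,
            "cv_high": self.cv_high, "cv_high_log_sd": self.cv_high_log_sd,
            "rho_high": self.rho_high, "rho_null": self.rho_null, "seed": self.seed,
        }


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n_genes + 1)]


def default_omics_truth(n_genes: int = 500, n_conserved: int = 50, n_correlated: int = 50,
                        overlap: int = 30, seed: int = 0, **kwargs) -> OmicsTruth:
    """Planted sets with a declared overlap (the doubly-planted genes first)."""
    ids = gene_ids(n_genes)
    if n_conserved + n_correlated - overlap > n_genes:
        raise ParameterError("planted sets exceed the gene universe")
    conserved = ids[:n_conserved]
    correlated = ids[n_conserved - overlap:n_conserved - overlap + n_correlated]
    return OmicsTruth(conserved_genes=tuple(conserved), correlated_genes=tuple(correlated),
                      seed=seed, **kwargs)


def generate_omics(n_genes: int, n_sites: int, n_patients: int, truth: OmicsTruth
                   ) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix]:
    """(site transcripts, patient transcripts, patient proteins), deterministic.

    Site transcript values are mu_g * (1 + cv_g * z); patient transcripts are
    standard normal; proteins are rho * transcript + sqrt(1 - rho^2) * noise,
    so the planted transcript-protein Spearman correlation is ~ the copula
    value (exactly 1 when rho = 1).
    """
    if n_sites < 2:
        raise ParameterError("n_sites must be >= 2 (between-site CV is undefined otherwise)")
    ids = gene_ids(n_genes)
    idset = set(ids)
    for name, planted in (("conserved", truth.conserved_genes),
                          ("correlated", truth.correlated_genes)):
        extra = set(planted) - idset
        if extra:
            raise ParameterError(f"{name} planted genes outside the universe: {sorted(extra)[:5]}")
        if len(planted) >= n_genes:
            raise ParameterError(f"{name} planted set must be smaller than n_genes")

    rng = np.random.default_rng(truth.seed)
    conserved = np.isin(ids, list(truth.conserved_genes))
    correlated = np.isin(ids, list(truth.correlated_genes))

    mu = np.exp(rng.normal(np.log(50.0), 0.3, size=n_genes))
    cv = np.where(
        conserved,
        np.abs(rng.normal(truth.cv_low, truth.cv_low_sd, size=n_genes)),
        np.exp(rng.normal(np.log(truth.cv_high), truth.cv_high_log_sd, size=n_genes)),
    )
    z_site = rng.standard_normal((n_genes, n_sites))
    site_vals = mu[:, None] * (1.0 + cv[:, None] * z_site)
    site_cols = ["primary"] + [f"met{i}" for i in range(1, n_sites)]
    site_tx = OmicsMatrix(pd.DataFrame(site_vals, index=ids, columns=site_cols),
                          kind="transcript")

    patients = [f"P{i:03d}" for i in range(1, n_patients + 1)]
    t = rng.standard_normal((n_genes, n_patients))
    noise = rng.standard_normal((n_genes, n_patients))
    rho = np.where(correlated, truth.rho_high, truth.rho_null)
    prot = rho[:, None] * t + np.sqrt(np.maximum(0.0, 1.0 - rho[:, None] ** 2)) * noise
    patient_tx = OmicsMatrix(pd.DataFrame(t, index=ids, columns=patients), kind="transcript")
    protein = OmicsMatrix(pd.DataFrame(prot, index=ids, columns=patients), kind="protein")
    return site_tx, patient_tx, protein


# ---------------------------------------------------------------------------
# traits

DEFAULT_TRAIT_SCHEMA: dict[str, TraitSpec] = {
    "disease_in_mesentery": TraitSpec("binary"),
    "supradiaphragmatic_lymphadenopathy": TraitSpec("binary"),
    "pouch_of_douglas_implants": TraitSpec("binary"),
    "peritoneal_disease_liver": TraitSpec("binary"),
    "discrete_ovarian_mass": TraitSpec("binary"),
    "n_sites_peritoneal_disease": TraitSpec("count"),
    "shape_of_peritoneal_disease": TraitSpec(
        "ordinal",
        levels=("diffuse", "predominantly_diffuse", "predominantly_nodular",
                "nodular", "no_peritoneal_disease")),
    "largest_lesion_mm": TraitSpec("quantitative", units="mm"),
}

# baseline generative parameters per default trait
_TRAIT_BASE = {
    "disease_in_mesentery": {"p0": 0.5},
    "supradiaphragmatic_lymphadenopathy": {"p0": 0.45},
    "pouch_of_douglas_implants": {"p0": 0.75},
    "peritoneal_disease_liver": {"p0": 0.7},
    "discrete_ovarian_mass": {"p0": 0.9},
    "n_sites_peritoneal_disease": {"lam0": 3.0},
    "shape_of_peritoneal_disease": {},
    "largest_lesion_mm": {"mu0": 63.0, "sd0": 20.0},
}


@dataclass(frozen=True)
class TraitTruth:
    """Planted protein-trait effects and reader-disagreement parameters.

    ``effects`` maps (protein gene id, trait name) to an effect magnitude on
    the trait's link scale; magnitude 0 (or absence) means the trait is
    generated independently of every protein.
    """

    effects: tuple = ()  # tuple of ((protein, trait), magnitude)
    disagreement_rate: float = 0.1
    reader_noise_sd: float = 3.0
    seed: int = 0

    def effect_map(self) -> dict:
        return {k: v for k, v in self.effects}

    def as_dict(self) -> dict:
        return {"effects": [[list(k), v] for k, v in self.effects],
                "disagreement_rate": self.disagreement_rate,
                "reader_noise_sd": self.reader_noise_sd, "seed": self.seed}


def _perturb_categorical(values: np.ndarray, n_levels: int, rate: float,
                         rng: np.random.Generator, kind: str) -> np.ndarray:
    """Symmetric label flips: binary flips, ordinal to a random other level,
    counts shifted by +-1 (floored at 0)."""
    out = values.copy()
    flip = rng.random(len(values)) < rate
    if kind == "binary":
        out[flip] = 1 - out[flip]
    elif kind == "ordinal":
        shift = rng.integers(1, n_levels, size=flip.sum())
        out[flip] = (out[flip] + shift) % n_levels
    else:  # count
        out[flip] = np.maximum(0, out[flip] + rng.choice([-1, 1], size=flip.sum()))
    return out


def generate_traits(protein_matrix: OmicsMatrix, truth: TraitTruth,
                    schema: dict[str, TraitSpec] | None = None
                    ) -> tuple[TraitTable, pd.DataFrame]:
    """Per-patient trait table with reader provenance, plus arbitration values.

    Returns (TraitTable with reader1/reader2/consolidated columns, a
    patients x traits frame of arbitrator values — the consolidated truth,
    which is what the third reader would report).
    """
    schema = dict(schema or DEFAULT_TRAIT_SCHEMA)
    effects = truth.effect_map()
    for (prot, trait) in effects:
        if trait not in schema:
            raise SchemaError(trait)
        if prot not in protein_matrix.gene_ids:
            raise ParameterError(f"planted protein {prot!r} not in the protein matrix")

    patients = list(protein_matrix.sample_ids)
    P = len(patients)
    rng = np.random.default_rng(truth.seed)

    def effect_z(trait: str) -> np.ndarray:
        z = np.zeros(P)
        for (prot, tr), mag in effects.items():
            if tr != trait or mag == 0:
                continue
            vals = protein_matrix.values.loc[prot].to_numpy(dtype=float)
            sd = vals.std()
            z = z + mag * (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        return z

    columns: dict[tuple[str, str], np.ndarray] = {}
    arbitration = {}
    for trait, spec in schema.items():
        base = _TRAIT_BASE.get(trait, {})
        z = effect_z(trait)
        if spec.kind == "binary":
            p0 = base.get("p0", 0.5)
            consolidated = (rng.random(P) < expit(logit(p0) + z)).astype(np.int64)
            n_levels = 2
        elif spec.kind == "count":
            lam0 = base.get("lam0", 3.0)
            consolidated = rng.poisson(np.exp(np.log(lam0) + 0.35 * z)).astype(np.int64)
            n_levels = int(consolidated.max()) + 1
        elif spec.kind == "ordinal":
            n_levels = len(spec.levels)
            latent = z + rng.standard_normal(P)
            # thresholds put equal baseline mass on each level
            from scipy.stats import norm
            cuts = norm.ppf(np.linspace(0, 1, n_levels + 1)[1:-1])
            consolidated = np.digitize(latent, cuts).astype(np.int64)
        else:  # quantitative
            mu0, sd0 = base.get("mu0", 0.0), base.get("sd0", 1.0)
            consolidated = mu0 + sd0 * (z + rng.standard_normal(P))

        if spec.kind == "quantitative":
            r1 = consolidated + rng.normal(0, truth.reader_noise_sd, P)
            r2 = consolidated + rng.normal(0, truth.reader_noise_sd, P)
        else:
            r1 = _perturb_categorical(consolidated, n_levels, truth.disagreement_rate,
                                      rng, spec.kind)
            r2 = _perturb_categorical(consolidated, n_levels, truth.disagreement_rate,
                                      rng, spec.kind)
        columns[(trait, "reader1")] = r1
        columns[(trait, "reader2")] = r2
        columns[(trait, "consolidated")] = consolidated
        arbitration[trait] = consolidated

    data = pd.DataFrame(columns, index=pd.Index(patients, name="patient"))
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["trait", "reader"])
    table = TraitTable(data, schema)
    arb = pd.DataFrame(arbitration, index=pd.Index(patients, name="patient"))
    return table, arb
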
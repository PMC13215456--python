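"""Synthetic fixtures with retained ground truth.

Three generators back the pipeline's test surface:

* :func:`make_slide` — an H&E-like stained image rendered through the same
  optical-density mixing model the stain-unmixing code inverts, with the
  tissue mask, nucleus geometry and true stain matrix kept as ground truth.
* :func:`make_cohort` — a multimodal cohort whose expression and pathomics
  features share latent factors, a subset of which drive proportional-hazards
  survival times.
* :func:`make_sc` — single-cell counts drawn from a known linear-SEM gene
  regulatory network, with quality-control violations planted at recorded
  cell indices.

All generators are pure functions of their arguments plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq

__all__ = [
    "SyntheticSlide",
    "SyntheticCohort",
    "SyntheticSCData",
    "DEFAULT_STAIN_MATRIX",
    "make_slide",
    "make_cohort",
    "make_sc",
]

# Standard H&E stain vectors (hematoxylin, eosin) as unit columns in OD space.
DEFAULT_STAIN_MATRIX = np.array(
    [[0.65, 0.07],
     [0.70, 0.99],
     [0.29, 0.11]]
)
DEFAULT_STAIN_MATRIX = DEFAULT_STAIN_MATRIX / np.linalg.norm(
    DEFAULT_STAIN_MATRIX, axis=0, keepdims=True
)


@dataclass
class SyntheticSlide:
    """Rendered stained image plus full ground truth."""

    image: np.ndarray          # H x W x 3 uint8
    tissue_mask: np.ndarray    # H x W bool
    nuclei: list               # (cx, cy, radius) tuples, pixel units
    stain_matrix_true: np.ndarray  # 3 x 2 unit columns (OD space)

    def __post_init__(self):
        if self.image.shape[:2] != self.tissue_mask.shape:
            raise ValueError("image and tissue_mask shapes differ")
        for cx, cy, r in self.nuclei:
            if not self.tissue_mask[int(round(cy)), int(round(cx))]:
                raise ValueError("nucleus center outside tissue mask")
            if not (3.0 < r <= 30.0):
                raise ValueError(f"nucleus radius {r} outside (3, 30] px")


@dataclass
class SyntheticCohort:
    n_samples: int
    z_true: np.ndarray         # n x k latent factors
    loadings_expr: np.ndarray  # k x d_expr
    loadings_path: np.ndarray  # k x d_path
    noise_sd: float
    beta_true: np.ndarray      # k hazard log-effects
    times: np.ndarray          # days, > 0
    events: np.ndarray         # {0,1}
    censor_rate: float
    expr: np.ndarray = field(default=None)  # n x d_expr observed
    path: np.ndarray = field(default=None)  # n x d_path observed
    sample_ids: list = field(default=None)


@dataclass
class SyntheticSCData:
    counts: np.ndarray         # genes x cells, nonnegative ints
    gene_names: list
    cell_names: list
    grn_true: np.ndarray       # genes x genes, zero diagonal, rows=regulators
    mito_fracs: np.ndarray     # per cell
    genes_detected: np.ndarray  # per cell
    planted_high_mito: np.ndarray  # cell indices
    planted_low_complexity: np.ndarray  # cell indices


def _smooth_field(shape, rng, sigma):
    f = rng.standard_normal(shape)
    f = ndi.gaussian_filter(f, sigma)
    return f


def make_slide(width=1024, height=1024, n_nuclei=20, tissue_coverage=0.6,
               seed=0, stain_matrix=None, min_separation=None,
               radius_range=(5.0, 12.0)):
    """Render a synthetic stained slide with known mask, nuclei and stains.

    The image is produced through the Beer-Lambert mixing model
    ``I = 256 * 10**(-S @ c) - 1`` with eosin concentration smooth over the
    tissue blob and hematoxylin concentrated in elliptical nuclei, so stain
    unmixing has a recoverable ground truth.

    Parameters
    ----------
    tissue_coverage : float in [0, 1]
        Target fraction of pixels covered by tissue; the rendered blob hits
        it to quantile precision.
    min_separation : float, optional
        Minimum center-to-center clearance beyond the sum of radii; defaults
        to 4 px, which keeps nuclei non-touching for segmentation fixtures.
    """
    if not 0.0 <= tissue_coverage <= 1.0:
        raise ValueError("tissue_coverage must be in [0, 1]")
    if width < 64 or height < 64:
        raise ValueError("slide dimensions must be >= 64 px")
    if n_nuclei > 0 and tissue_coverage == 0.0:
        raise ValueError("cannot place nuclei with zero tissue coverage")
    rng = np.random.default_rng(seed)
    S = DEFAULT_STAIN_MATRIX if stain_matrix is None else np.asarray(stain_matrix, float)
    S = S / np.linalg.norm(S, axis=0, keepdims=True)

    # Tissue blob: threshold a smoothed Gaussian field at the coverage quantile.
    if tissue_coverage == 0.0:
        mask = np.zeros((height, width), bool)
    elif tissue_coverage == 1.0:
        mask = np.ones((height, width), bool)
    else:
        f = _smooth_field((height, width), rng, sigma=min(height, width) / 8)
        thr = np.quantile(f, 1.0 - tissue_coverage)
        mask = f > thr

    # Concentration maps (hematoxylin, eosin).
    c_h = np.zeros((height, width))
    c_e = np.zeros((height, width))
    if mask.any():
        tex = _smooth_field((height, width), rng, sigma=12)
        tex = (tex - tex.min()) / (np.ptp(tex) + 1e-12)
        c_e[mask] = 1.0 + 0.8 * tex[mask]
        c_h[mask] = 0.05

    # Place non-touching elliptical nuclei inside the mask, away from its edge.
    sep = 4.0 if min_separation is None else float(min_separation)
    inner = ndi.binary_erosion(mask, iterations=int(radius_range[1]) + 2) if mask.any() else mask
    ys, xs = np.nonzero(inner)
    nuclei = []
    if n_nuclei > 0:
        if len(ys) == 0:
            raise ValueError("tissue blob too small to place nuclei")
        yy, xx = np.mgrid[0:height, 0:width]
        attempts = 0
        while len(nuclei) < n_nuclei:
            attempts += 1
            if attempts > 200 * n_nuclei:
                raise ValueError("could not place requested nuclei count")
            j = rng.integers(len(ys))
            cx, cy = float(xs[j]), float(ys[j])
            r = float(rng.uniform(*radius_range))
            if any(np.hypot(cx - px, cy - py) < r + pr + sep for px, py, pr in nuclei):
                continue
            nuclei.append((cx, cy, r))
            ratio = rng.uniform(0.7, 1.0)
            theta = rng.uniform(0, np.pi)
            a, b = r, r * ratio
            dx, dy = xx - cx, yy - cy
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            # chromatin-dense nuclei: hematoxylin-dominant, eosin displaced
            c_h[inside] += 1.1
            c_e[inside] *= 0.08
    od = S[:, 0][:, None, None] * c_h[None] + S[:, 1][:, None, None] * c_e[None]
    intensity = 256.0 * np.power(10.0, -od) - 1.0
    image = np.clip(np.rint(np.moveaxis(intensity, 0, -1)), 0, 255).astype(np.uint8)
    return SyntheticSlide(image=image, tissue_mask=mask, nuclei=nuclei,
                          stain_matrix_true=S)


def make_stain_mixture(shape=(300, 300), stain_matrix=None, seed=0,
                       mag_range=(0.4, 2.5)):
    """Image of random two-stain OD mixtures with near-pure pixels.

    Per-pixel concentrations are a magnitude drawn uniformly from
    ``mag_range`` times a U-shaped Beta(0.3, 0.3) mixing fraction, so both
    pure-stain directions are well represented — the fixture stain
    estimation is benchmarked against. Returns (image uint8, stain matrix).
    """
    rng = np.random.default_rng(seed)
    S = DEFAULT_STAIN_MATRIX if stain_matrix is None else np.asarray(stain_matrix, float)
    S = S / np.linalg.norm(S, axis=0, keepdims=True)
    n = shape[0] * shape[1]
    frac = rng.beta(0.3, 0.3, n)
    mag = rng.uniform(*mag_range, n)
    conc = np.column_stack([mag * frac, mag * (1.0 - frac)])
    od = conc @ S.T
    img = np.clip(np.rint(256.0 * np.power(10.0, -od) - 1.0), 0, 255)
    return img.astype(np.uint8).reshape(*shape, 3), S


def _solve_censor_rate(hazards, target, lo=1e-10, hi=1e4):
    """Exponential censoring rate c with mean(c / (c + lambda_i)) == target."""
    def f(logc):
        c = np.exp(logc)
        return np.mean(c / (c + hazards)) - target
    return np.exp(brentq(f, np.log(lo), np.log(hi)))


def make_cohort(n=400, k=4, d_expr=30, d_path=20, beta_true=None,
                noise_sd=0.2, censor_rate=0.3, seed=0, baseline_hazard=0.01):
    """Latent-factor cohort with proportional-hazards survival.

    ``z ~ N(0, I)``; event times are exponential with hazard
    ``h0 * exp(z @ beta_true)`` (h0 = 0.01 / day); censoring times are
    exponential with rate solved numerically so the expected censored
    fraction equals ``censor_rate``. Observed features are
    ``z @ loadings + noise_sd * N(0, 1)`` per modality.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    if k < 1:
        raise ValueError("k must be >= 1")
    if censor_rate >= 1.0 or censor_rate < 0.0:
        raise ValueError("censor_rate must be in [0, 1)")
    beta_true = np.zeros(k) if beta_true is None else np.asarray(beta_true, float)
    if beta_true.shape != (k,):
        raise ValueError("beta_true must have length k")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k))
    L_e = rng.standard_normal((k, d_expr)) / np.sqrt(k)
    L_p = rng.standard_normal((k, d_path)) / np.sqrt(k)
    expr = z @ L_e + noise_sd * rng.standard_normal((n, d_expr))
    path = z @ L_p + noise_sd * rng.standard_normal((n, d_path))

    hazards = baseline_hazard * np.exp(z @ beta_true)
    t_event = rng.exponential(1.0 / hazards)
    if censor_rate == 0.0:
        times, events = t_event, np.ones(n, int)
    else:
        c_rate = _solve_censor_rate(hazards, censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
    times = np.maximum(times, 1e-6)
    ids = [f"S{i:04d}" for i in range(n)]
    return SyntheticCohort(
        n_samples=n, z_true=z, loadings_expr=L_e, loadings_path=L_p,
        noise_sd=noise_sd, beta_true=beta_true, times=times, events=events,
        censor_rate=censor_rate, expr=expr, path=path, sample_ids=ids,
    )


def grn_from_edges(n_genes, edges):
    """Dense regulator-by-target adjacency from a signed edge list."""
    W = np.zeros((n_genes, n_genes))
    for i, j, w in edges:
        if i == j:
            raise ValueError("self-loops not allowed")
        W[i, j] = w
    return W


def make_sc(n_genes=20, n_cells=1000, grn_spec=(), seed=0,
            n_mito_genes=2, base_log_mean=2.0, sem_scale=1.0,
            n_high_mito=0, n_low_complexity=0, libsize_sigma=0.3,
            qc_max_mito=0.10):
    """Single-cell counts from a linear-SEM GRN with planted QC violations.

    Each cell's latent expression solves ``x = W^T x + eps`` with
    ``eps ~ N(0, 1)``; Poisson rates are ``exp(sem_scale * x + base_log_mean)``
    scaled by a lognormal(0, ``libsize_sigma``) library-size factor. The first
    ``n_mito_genes`` genes are named with the MT- prefix. Cells listed in
    ``planted_high_mito`` get mitochondrial counts boosted above any sane QC
    cut; ``planted_low_complexity`` cells keep only a couple of detected
    genes.
    """
    rng = np.random.default_rng(seed)
    W = grn_from_edges(n_genes, grn_spec) if not isinstance(grn_spec, np.ndarray) else grn_spec.copy()
    if np.any(np.diag(W) != 0):
        raise ValueError("GRN diagonal must be zero")
    rho = np.max(np.abs(np.linalg.eigvals(W)))
    if rho >= 1.0:
        raise ValueError(f"SEM spectral radius {rho:.3f} >= 1; system unstable")

    eps = rng.standard_normal((n_genes, n_cells))
    x = np.linalg.solve(np.eye(n_genes) - W.T, eps)
    lib = np.exp(rng.normal(0.0, libsize_sigma, size=n_cells))
    rate = np.exp(sem_scale * x + base_log_mean) * lib[None, :]
    counts = rng.poisson(rate).astype(np.int64)

    gene_names = [f"MT-G{i}" if i < n_mito_genes else f"G{i}" for i in range(n_genes)]
    cell_names = [f"C{j}" for j in range(n_cells)]

    bad = rng.permutation(n_cells)[: n_high_mito + n_low_complexity]
    high_mito = np.sort(bad[:n_high_mito])
    low_complex = np.sort(bad[n_high_mito:])
    if n_mito_genes == 0 and n_high_mito > 0:
        raise ValueError("cannot plant high-mito cells without mito genes")
    # keep naturally high-mito cells safely under the QC cut so the planted
    # set is exactly the violating set
    if n_mito_genes:
        clean = np.ones(n_cells, bool)
        clean[bad] = False
        tot = counts.sum(axis=0)
        mf = counts[:n_mito_genes].sum(axis=0) / np.maximum(tot, 1)
        for j in np.nonzero(clean & (mf > 0.8 * qc_max_mito))[0]:
            cap = int(0.5 * qc_max_mito * tot[j] / max(n_mito_genes, 1))
            counts[:n_mito_genes, j] = np.minimum(counts[:n_mito_genes, j], cap)
    for j in high_mito:
        # mito counts dominate the cell: fraction well above the QC cut
        counts[:n_mito_genes, j] += int(counts[:, j].sum() * 2 + 10)
    for j in low_complex:
        keep = rng.permutation(n_genes)[:2]
        zeroed = np.ones(n_genes, bool)
        zeroed[keep] = False
        counts[zeroed, j] = 0
        counts[keep, j] = np.maximum(counts[keep, j], 1)

    totals = counts.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    mito_fracs = counts[:n_mito_genes].sum(axis=0) / totals
    genes_detected = (counts > 0).sum(axis=0)
    return SyntheticSCData(
        counts=counts, gene_names=gene_names, cell_names=cell_names,
        grn_true=W, mito_fracs=mito_fracs, genes_detected=genes_detected,
        planted_high_mito=high_mito, planted_low_complexity=low_complex,
    )
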
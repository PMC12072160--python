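"""Synthetic data generators for both analysis tracks.

``simulate_peptide_table`` emulates a label-free secretome experiment:
log-normal protein abundances measured in analytical triplicate per
condition, condition-specific multiplicative effects, and whole-condition
dropout that produces Venn-exclusive identifications.  ``top3_quantify``
performs the top-3 LFQ aggregation from peptide precursor areas to
protein abundances.  ``simulate_fiber_image`` renders filament images as
sums of oriented line segments whose (axial) orientations follow a
von Mises distribution with concentration kappa — isotropic at kappa=0,
aligned at large kappa — plus Gaussian noise.

Every generator takes an explicit seed and draws from its own RNG stream;
identical parameters and seed give bit-identical output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CONDITIONS, AbundanceMatrix, FiberImage, PeptideTable

__all__ = [
    "SecretomeSimParams",
    "FiberSimParams",
    "simulate_peptide_table",
    "top3_quantify",
    "simulate_fiber_image",
    "save_fiber_image",
]


@dataclass
class SecretomeSimParams:
    """Generative parameters for the synthetic secretome.

    Defaults emulate the scale of the real experiment: a few hundred
    secreted proteins identified per comparison, measured in analytical
    triplicate, with ~10% of proteins dropping out of a whole condition
    (the source of exclusive Venn classes) and a 20% replicate CV, a
    typical technical-replicate spread for label-free quantification.
    """

    n_proteins: int = 500
    peptides_per_protein: tuple[int, int] = (2, 8)
    base_abundance_loc: float = 13.8  # log-scale location, ~1e6 area units
    base_abundance_scale: float = 1.5
    peptide_scale: float = 0.7  # log-sd of per-peptide ionization factor
    effect_map: dict = field(default_factory=dict)  # protein -> {condition: fold}
    replicate_cv: float = 0.2
    dropout_rate: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_protein must be a range (lo, hi), lo >= 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        for prot, effects in self.effect_map.items():
            for cond, e in effects.items():
                if cond not in CONDITIONS:
                    raise ValueError(f"unknown condition {cond!r} for {prot!r}")
                if e <= 0:
                    raise ValueError("effects must be > 0")


def simulate_peptide_table(params: SecretomeSimParams) -> PeptideTable:
    """Draw a peptide-level precursor-area table.

    Each protein gets a log-normal base abundance and a log-normal
    per-peptide ionization factor; each condition multiplies the protein
    by its effect (1 for unlisted protein/condition pairs, always 1 for
    CTR); each replicate multiplies by a mean-one log-normal noise term
    with the requested CV.  A protein flagged for dropout in a condition
    is missing (NaN) in all replicates of that condition for all its
    peptides, so its expected log2 ratio of any condition mean to the CTR
    mean equals log2(effect).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    p = params

    protein_ids = [f"P{i:04d}" for i in range(p.n_proteins)]
    lo, hi = p.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=p.n_proteins)
    base = np.exp(rng.normal(p.base_abundance_loc, p.base_abundance_scale, p.n_proteins))

    # mean-one multiplicative replicate noise with the requested CV
    sigma = np.sqrt(np.log1p(p.replicate_cv**2))

    dropped = pd.DataFrame(
        rng.random((p.n_proteins, len(CONDITIONS))) < p.dropout_rate,
        index=protein_ids,
        columns=list(CONDITIONS),
    )

    samples = [f"{c}_{r}" for c in CONDITIONS for r in range(1, p.n_replicates + 1)]
    rows = []
    for i, prot in enumerate(protein_ids):
        pep_factor = np.exp(rng.normal(0.0, p.peptide_scale, n_pep[i]))
        effects = p.effect_map.get(prot, {})
        for j in range(n_pep[i]):
            row: dict = {"protein_id": prot, "peptide_id": f"{prot}_pep{j}"}
            for c in CONDITIONS:
                eff = 1.0 if c == "CTR" else float(effects.get(c, 1.0))
                for r in range(1, p.n_replicates + 1):
                    if dropped.at[prot, c]:
                        row[f"{c}_{r}"] = np.nan
                    else:
                        noise = np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0)
                        row[f"{c}_{r}"] = base[i] * pep_factor[j] * eff * noise
            rows.append(row)
    df = pd.DataFrame(rows, columns=["protein_id", "peptide_id", *samples])
    return PeptideTable(df=df, dropped=dropped)


def top3_quantify(table: PeptideTable) -> AbundanceMatrix:
    """Top-3 label-free quantification.

    The protein abundance in a sample is the mean of its three largest
    non-missing peptide precursor areas; with fewer than three observed
    peptides the mean of those observed is used, and a protein with no
    observed peptide in a sample is missing there.
    """
    if table.df.empty:
        raise ValueError("empty peptide table")
    samples = table.sample_columns

    def top3(col: pd.Series) -> float:
        obs = col.dropna().to_numpy()
        if obs.size == 0:
            return np.nan
        k = min(3, obs.size)
        return float(np.mean(np.sort(obs)[-k:]))

    grouped = table.df.groupby("protein_id", sort=False)
    values = grouped[samples].agg(top3)
    unique_peptides = grouped["peptide_id"].nunique()
    return AbundanceMatrix(values=values, unique_peptides=unique_peptides)


@dataclass
class FiberSimParams:
    """Generative parameters for synthetic filament images.

    Fibers are straight segments with a Gaussian cross-section of full
    width ``fiber_width`` whose orientations are axial (theta and
    theta+pi identical) and von Mises distributed around
    ``mean_orientation`` with concentration ``kappa``.  Segment length is
    not a property of the real measurement being emulated; it defaults
    to half the smaller image dimension so that fibers span several
    analysis windows.
    """

    width: int = 256
    height: int = 256
    n_fibers: int = 150
    kappa: float = 0.0
    mean_orientation: float = 0.0  # radians in [0, pi), fiber axis
    fiber_width: float = 3.0
    fiber_intensity: float = 100.0
    background: float = 10.0
    noise_sd: float = 5.0
    fiber_length: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.width < 128 or self.height < 128:
            raise ValueError("image must be at least 128x128 so 100x100 ROIs fit")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.fiber_width <= 0:
            raise ValueError("fiber_width must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sample_axial_von_mises(rng: np.random.Generator, mean: float, kappa: float, n: int) -> np.ndarray:
    """Axial (pi-periodic) von Mises angles: sample on the doubled circle, halve."""
    theta2 = rng.vonmises(2.0 * mean, kappa, size=n)
    return (theta2 / 2.0) % np.pi


def simulate_fiber_image(params: FiberSimParams) -> FiberImage:
    """Render a synthetic filament image.

    kappa=0 gives uniformly distributed fiber orientations (isotropic
    texture); large kappa aligns all fibers near ``mean_orientation``.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)

    img = np.zeros((p.height, p.width), dtype=float)
    length = p.fiber_length if p.fiber_length is not None else 0.5 * min(p.height, p.width)
    sigma = p.fiber_width / 2.0
    pad = 3.0 * sigma

    thetas = _sample_axial_von_mises(rng, p.mean_orientation, p.kappa, p.n_fibers)
    cx = rng.uniform(0, p.width, p.n_fibers)
    cy = rng.uniform(0, p.height, p.n_fibers)

    for theta, x0, y0 in zip(thetas, cx, cy):
        # orientation measured from the column (x) axis; rows are y
        dx, dy = np.cos(theta), np.sin(theta)
        x1, y1 = x0 - dx * length / 2, y0 - dy * length / 2
        x2, y2 = x0 + dx * length / 2, y0 + dy * length / 2
        rmin = max(int(np.floor(min(y1, y2) - pad)), 0)
        rmax = min(int(np.ceil(max(y1, y2) + pad)) + 1, p.height)
        cmin = max(int(np.floor(min(x1, x2) - pad)), 0)
        cmax = min(int(np.ceil(max(x1, x2) + pad)) + 1, p.width)
        if rmin >= rmax or cmin >= cmax:
            continue
        yy, xx = np.mgrid[rmin:rmax, cmin:cmax]
        vx, vy = x2 - x1, y2 - y1
        seg2 = vx * vx + vy * vy
        t = ((xx - x1) * vx + (yy - y1) * vy) / seg2
        t = np.clip(t, 0.0, 1.0)
        d2 = (xx - (x1 + t * vx)) ** 2 + (yy - (y1 + t * vy)) ** 2
        img[rmin:rmax, cmin:cmax] += p.fiber_intensity * np.exp(-d2 / (2.0 * sigma**2))

    img += p.background
    if p.noise_sd > 0:
        img += rng.normal(0.0, p.noise_sd, img.shape)
    np.clip(img, 0.0, None, out=img)
    return FiberImage(pixels=img, provenance=f"synthetic von Mises fibers, kappa={p.kappa}, seed={p.seed}")


def save_fiber_image(image: FiberImage, path, bit_depth: int = 16) -> None:
    """Write a grayscale TIFF/PNG with the linear scaling recorded in a JSON sidecar."""
    import tifffile
    from PIL import Image

    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    vmax = float(image.pixels.max())
    top = (1 << bit_depth) - 1
    scale = top / vmax if vmax > 0 else 1.0
    arr = np.round(image.pixels * scale).astype(np.uint16 if bit_depth == 16 else np.uint8)
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)
    with open(path + ".json", "w") as fh:
        json.dump({"scale": scale, "bit_depth": bit_depth, "provenance": image.provenance}, fh)
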
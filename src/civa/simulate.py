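"""Seeded synthetic-data generators with full ground truth.

Three generators emulate the statistical structure the analysis assumes:

* :func:`sim_image_stack` renders two-channel 4D stacks of a disk-shaped
  cell containing diffraction-limited sister-kinetochore pairs — isotropic
  2D Gaussian spots per Z plane with a Gaussian z-attenuation, sinusoidal
  "breathing" of the pair separation, optional drift, and a
  Poisson-then-Gaussian camera noise model on top of a flat cytoplasm and
  integer camera offset. Spot amplitudes are set so that the mean intensity
  over a spot's half-maximum (FWHM) footprint gives exactly the configured
  kinetochore/cytoplasm ratio after background subtraction; the truth table
  carries per-frame centroids, identities, pair memberships, d(t) and the
  true ratios, plus the FWHM truth masks.

* :func:`sim_variant_table` draws genotype counts under an inbreeding
  coefficient F (genotype frequencies AA: (1-q)^2 + q(1-q)F,
  Aa: 2q(1-q)(1-F), aa: q^2 + q(1-q)F), with rare allele frequencies from
  a Beta distribution truncated to (0, 0.05], and marks which variants
  satisfy the CIVa prevalence rule.

* :func:`sim_timing` draws mitotic NEBD->AO durations from a parametric
  distribution, rounds them up to the acquisition frame grid (6 min
  default) and censors at the imaging window (10 h default).

Every generator is a pure function of its config including the seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .quantify import ImageStack, LabelMask
from .timing import MitoticEventRecord
from .variants import VariantRecord

__all__ = [
    "ImageSimConfig",
    "VariantSimConfig",
    "ImageTruth",
    "sim_image_stack",
    "sim_variant_table",
    "sim_timing",
    "sim_motion",
    "make_kozak_cds",
    "random_cds",
]


# ---------------------------------------------------------------------------
# image stacks


@dataclass
class ImageSimConfig:
    """Rendering parameters for a synthetic two-channel acquisition.

    Defaults emulate a 100x metaphase acquisition: 0.1 µm pixels, 3 Z
    planes 0.6 µm apart, 6-min frames, ~24 kinetochores as sister pairs
    with baseline separation 1.2 µm breathing by ±0.3 µm.
    """

    n_pairs: int = 12
    pair_separation_um: float = 1.2
    breathing_amplitude_um: float = 0.3
    breathing_period_frames: float = 8.0
    spot_sigma_px: float = 1.5
    spot_amplitude_ref: float | None = None   # derived from true_ratio_ref if None
    true_ratio_ref: float = 3.0
    true_ratio_meas: float = 2.0
    cell_radius_px: int = 85
    image_shape: tuple[int, int] = (200, 200)
    cytoplasm_level: float = 200.0
    camera_offset: int = 100
    gaussian_sigma: float = 0.0
    snr: float | None = None          # overrides gaussian_sigma as amplitude/snr
    poisson: bool = False
    drift_px_per_frame: float = 0.0
    ratio_decay_per_frame: float = 0.0  # linear fade of the measurement ratio
    n_frames: int = 10
    n_z: int = 3
    z_sigma_planes: float = 1.0
    pixel_size_um: float = 0.1
    z_step_um: float = 0.6
    frame_interval_min: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pair_separation_um", "spot_sigma_px", "cell_radius_px",
                     "cytoplasm_level", "pixel_size_um", "true_ratio_ref",
                     "true_ratio_meas", "n_pairs", "n_frames", "n_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ImageTruth:
    """Ground truth accompanying a rendered stack."""

    spots: pd.DataFrame   # frame, spot_id, pair_id, y_px, x_px, true_ratio_ref, true_ratio_meas
    pairs: pd.DataFrame   # frame, pair_id, d_um
    label_masks: list[np.ndarray] = field(repr=False, default_factory=list)

    def mask(self, frame: int) -> LabelMask:
        """Truth FWHM footprints of frame ``frame`` as a LabelMask."""
        labels = self.label_masks[frame]
        sub = self.spots[self.spots.frame == frame]
        table = pd.DataFrame(
            {
                "label": sub.spot_id.to_numpy() + 1,
                "area_px": [int((labels == s + 1).sum()) for s in sub.spot_id],
                "y_px": sub.y_px.to_numpy(),
                "x_px": sub.x_px.to_numpy(),
            }
        )
        return LabelMask(labels=labels, table=table)


def _gaussian_patch(shape: tuple[int, int], y: float, x: float, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2))


def _place_pair_centers(cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample pair centers inside the cell with safe spacing."""
    max_sep_px = (cfg.pair_separation_um + cfg.breathing_amplitude_um) / cfg.pixel_size_um
    margin = max_sep_px / 2 + 3 * cfg.spot_sigma_px + abs(cfg.drift_px_per_frame) * cfg.n_frames + 2
    rmax = cfg.cell_radius_px - margin
    if rmax <= 0:
        raise ValueError("spots outside cell: cell too small for configured separation/drift")
    min_spacing = max_sep_px + 6 * cfg.spot_sigma_px
    cy, cx = (cfg.image_shape[0] - 1) / 2, (cfg.image_shape[1] - 1) / 2
    centers: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(centers) == cfg.n_pairs:
            break
        r = rmax * np.sqrt(rng.random())
        th = rng.random() * 2 * np.pi
        cand = (cy + r * np.sin(th), cx + r * np.cos(th))
        if all(np.hypot(cand[0] - y, cand[1] - x) >= min_spacing for y, x in centers):
            centers.append(cand)
    if len(centers) < cfg.n_pairs:
        raise ValueError("could not place all pairs inside the cell; reduce n_pairs")
    return np.asarray(centers)


def sim_image_stack(cfg: ImageSimConfig) -> tuple[ImageStack, ImageTruth]:
    """Render a synthetic acquisition and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.image_shape
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    yy, xx = np.mgrid[0:ny, 0:nx]
    cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.cell_radius_px**2

    centers = _place_pair_centers(cfg, rng)
    angles = rng.random(cfg.n_pairs) * 2 * np.pi

    sigma_noise = cfg.gaussian_sigma
    zc = (cfg.n_z - 1) / 2
    z_fac = np.exp(-((np.arange(cfg.n_z) - zc) ** 2) / (2 * cfg.z_sigma_planes**2))

    data = np.zeros((cfg.n_frames, cfg.n_z, 2, ny, nx), dtype=float)
    spot_rows, pair_rows, truth_masks = [], [], []
    amp_meas_nominal = None
    for t in range(cfg.n_frames):
        d_um = cfg.pair_separation_um + cfg.breathing_amplitude_um * np.sin(
            2 * np.pi * t / cfg.breathing_period_frames
        )
        half_px = d_um / (2 * cfg.pixel_size_um)
        drift = cfg.drift_px_per_frame * t
        ref_plane = np.zeros((ny, nx))
        meas_plane = np.zeros((ny, nx))
        labels = np.zeros((ny, nx), dtype=np.int32)
        ratio_meas_t = cfg.true_ratio_meas - cfg.ratio_decay_per_frame * t
        if ratio_meas_t <= 0.0:
            raise ValueError("ratio decay drives the measurement ratio to <= 0")
        for p in range(cfg.n_pairs):
            oy, ox = np.sin(angles[p]) * half_px, np.cos(angles[p]) * half_px
            for s, sign in enumerate((-1, 1)):
                y = centers[p, 0] + sign * oy
                x = centers[p, 1] + sign * ox + drift
                if (y - cy) ** 2 + (x - cx) ** 2 > (cfg.cell_radius_px - 2 * cfg.spot_sigma_px) ** 2:
                    raise ValueError("spots outside cell")
                g = _gaussian_patch((ny, nx), y, x, cfg.spot_sigma_px)
                fwhm = g >= 0.5
                gbar = g[fwhm].mean()
                # amplitude chosen so that, after mean projection over Z,
                # the mean over the FWHM footprint hits the configured ratio
                zbar = float(z_fac.mean())
                amp_meas = (ratio_meas_t - 1.0) * cfg.cytoplasm_level / (gbar * zbar)
                if cfg.spot_amplitude_ref is not None:
                    amp_ref = cfg.spot_amplitude_ref
                else:
                    amp_ref = (cfg.true_ratio_ref - 1.0) * cfg.cytoplasm_level / (gbar * zbar)
                ref_plane += amp_ref * g
                meas_plane += amp_meas * g
                spot_id = 2 * p + s
                labels[fwhm] = spot_id + 1
                if t == 0 and amp_meas_nominal is None:
                    amp_meas_nominal = amp_meas
                spot_rows.append(
                    {"frame": t, "spot_id": spot_id, "pair_id": p,
                     "y_px": y, "x_px": x,
                     "true_ratio_ref": cfg.true_ratio_ref,
                     "true_ratio_meas": ratio_meas_t}
                )
        pair_rows.extend(
            {"frame": t, "pair_id": p, "d_um": d_um} for p in range(cfg.n_pairs)
        )
        truth_masks.append(labels)
        cyto = cell * cfg.cytoplasm_level
        for z in range(cfg.n_z):
            data[t, z, 0] = cyto + z_fac[z] * ref_plane
            data[t, z, 1] = cyto + z_fac[z] * meas_plane

    if cfg.snr is not None:
        sigma_noise = float(amp_meas_nominal) / cfg.snr
    if cfg.poisson:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if sigma_noise > 0:
        data = data + rng.normal(0.0, sigma_noise, size=data.shape)
    data = data + cfg.camera_offset

    stack = ImageStack(
        data=data,
        channel_names=["CENPB", "YFP"],
        pixel_size_um=cfg.pixel_size_um,
        z_step_um=cfg.z_step_um,
        frame_interval_min=cfg.frame_interval_min,
        reference_channel="CENPB",
        measurement_channel="YFP",
    )
    truth = ImageTruth(
        spots=pd.DataFrame(spot_rows),
        pairs=pd.DataFrame(pair_rows),
        label_masks=truth_masks,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# variant tables


@dataclass
class VariantSimConfig:
    """Population-genetic parameters for a synthetic variant table.

    ``inbreeding_f`` reproduces the excess homozygosity of cohorts with
    elevated parental relatedness; allele frequencies are Beta(0.5, 10)
    truncated to (0, 0.05] to emulate rare LoF variants.
    """

    n_genes: int = 20
    variants_per_gene: int = 4
    n_individuals: int = 5000
    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "stop_gain": 0.2, "frameshift": 0.2, "missense": 0.45, "synonymous": 0.15,
        }
    )
    inbreeding_f: float = 0.0
    beta_a: float = 0.5
    beta_b: float = 10.0
    af_max: float = 0.05
    protein_length: int = 1200
    source: str = "SIM"
    min_individuals: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.inbreeding_f <= 1:
            raise ValueError("inbreeding_f must be in [0, 1]")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")


_AA_POOL = "ARNDCQEGHILKMFPSTWYV"


def _random_hgvs(cls: str, rng: np.random.Generator, protein_length: int) -> str:
    pos = int(rng.integers(2, protein_length))
    ref = _AA_POOL[rng.integers(len(_AA_POOL))]
    if cls == "stop_gain":
        return f"{ref}{pos}*"
    if cls == "frameshift":
        alt = _AA_POOL[rng.integers(len(_AA_POOL))]
        n = int(rng.integers(2, 40))
        return f"{ref}{pos}{alt}fs*{n}"
    if cls == "missense":
        alt = ref
        while alt == ref:
            alt = _AA_POOL[rng.integers(len(_AA_POOL))]
        return f"{ref}{pos}{alt}"
    return f"{ref}{pos}="


def genotype_frequencies(q: float, f: float) -> tuple[float, float, float]:
    """(AA, Aa, aa) frequencies at minor-allele frequency q with inbreeding F."""
    aa_hom = q * q + q * (1 - q) * f
    het = 2 * q * (1 - q) * (1 - f)
    return 1 - het - aa_hom, het, aa_hom


def sim_variant_table(cfg: VariantSimConfig) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Draw a variant table and the truth flags of the CIVa rule."""
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.class_probs)
    probs = np.array([cfg.class_probs[c] for c in classes])
    records, truth_rows = [], []
    letters = string.ascii_uppercase
    for g in range(cfg.n_genes):
        gene = f"SEG{letters[g % 26]}{g + 1:03d}"
        seen = set()
        for _ in range(cfg.variants_per_gene):
            cls = classes[rng.choice(len(classes), p=probs)]
            hgvs = _random_hgvs(cls, rng, cfg.protein_length)
            while (gene, hgvs) in seen:
                hgvs = _random_hgvs(cls, rng, cfg.protein_length)
            seen.add((gene, hgvs))
            q = 0.0
            while not (0 < q <= cfg.af_max):
                q = rng.beta(cfg.beta_a, cfg.beta_b)
            p_aa, p_het, p_hom = genotype_frequencies(q, cfg.inbreeding_f)
            n_aa, n_het, n_hom = rng.multinomial(cfg.n_individuals, [p_aa, p_het, p_hom])
            rec = VariantRecord(
                gene_symbol=gene,
                hgvs_p=hgvs,
                counts={cfg.source: (int(n_het), int(n_hom))},
                uniprot_id=f"P{g:05d}",
                protein_length=cfg.protein_length,
            )
            records.append(rec)
            truth_rows.append(
                {
                    "gene": gene, "hgvs_p": hgvs, "class": cls, "q_true": q,
                    "het": int(n_het), "hom": int(n_hom),
                    "is_civa": cls in ("stop_gain", "frameshift")
                    and (n_het + n_hom) >= cfg.min_individuals,
                }
            )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# mitotic timing


def sim_timing(
    distribution: tuple[str, dict],
    n_cells: int,
    frame_interval_min: float = 6.0,
    window_min: float = 600.0,
    seed: int = 0,
    condition: str = "SIM",
    replicate_id: str = "rep1",
) -> tuple[list[MitoticEventRecord], dict]:
    """Draw NEBD->AO durations, quantize to the frame grid, censor at the window.

    ``distribution`` is ("exponential", {"median": m}), ("fixed",
    {"value": v}) or ("lognormal", {"median": m, "sigma": s}). Durations
    are rounded *up* to the next acquired frame (an event is only seen at
    the first frame after it happens). Truth records the generating median.
    """
    rng = np.random.default_rng(seed)
    name, params = distribution
    if name == "exponential":
        median = float(params["median"])
        raw = rng.exponential(median / np.log(2), size=n_cells)
    elif name == "fixed":
        median = float(params["value"])
        raw = np.full(n_cells, median)
    elif name == "lognormal":
        median = float(params["median"])
        raw = rng.lognormal(np.log(median), float(params.get("sigma", 0.5)), size=n_cells)
    else:
        raise ValueError(f"unknown distribution {name!r}")
    quant = np.ceil(raw / frame_interval_min) * frame_interval_min
    quant = np.maximum(quant, frame_interval_min)
    records = []
    for i, t in enumerate(quant):
        completed = t <= window_min
        records.append(
            MitoticEventRecord(
                cell_id=f"cell{i:04d}",
                condition=condition,
                replicate_id=replicate_id,
                t_NEBD=0.0,
                t_AO=float(t) if completed else None,
                completed=bool(completed),
            )
        )
    truth = {"median": median, "frame_interval_min": frame_interval_min,
             "window_min": window_min, "n_cells": n_cells}
    return records, truth


# ---------------------------------------------------------------------------
# point motion (for linking tests) and CDS builders


def sim_motion(
    n_particles: int = 50,
    n_frames: int = 30,
    step_px: float = 1.0,
    min_spacing_px: float = 10.0,
    box: tuple[float, float] = (400.0, 400.0),
    seed: int = 0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Random-walk point motion with guaranteed initial spacing.

    Returns per-frame centroid arrays (rows shuffled, so detection order
    carries no identity information) and a truth table (frame, particle_id,
    y_px, x_px, row) mapping shuffled rows back to identities.
    """
    rng = np.random.default_rng(seed)
    pts: list[tuple[float, float]] = []
    margin = step_px * n_frames + 5
    for _ in range(100000):
        if len(pts) == n_particles:
            break
        cand = (margin + rng.random() * (box[0] - 2 * margin),
                margin + rng.random() * (box[1] - 2 * margin))
        if all(np.hypot(cand[0] - y, cand[1] - x) >= min_spacing_px for y, x in pts):
            pts.append(cand)
    if len(pts) < n_particles:
        raise ValueError("could not place particles with requested spacing")
    pos = np.asarray(pts)
    frames, rows = [], []
    for t in range(n_frames):
        if t:
            steps = rng.normal(0, step_px / np.sqrt(2), size=pos.shape)
            norms = np.hypot(steps[:, 0], steps[:, 1])
            too_big = norms > step_px
            if too_big.any():  # cap step length so spacing stays safe
                steps[too_big] *= (step_px / norms[too_big])[:, None]
            pos = pos + steps
        order = rng.permutation(n_particles)
        frames.append(pos[order].copy())
        for row, pid in enumerate(order):
            rows.append({"frame": t, "particle_id": int(pid), "row": row,
                         "y_px": pos[pid, 0], "x_px": pos[pid, 1]})
    return frames, pd.DataFrame(rows)


def random_cds(length_codons: int, rng: np.random.Generator) -> str:
    """Random ATG-initiated CDS (uniform codons, no stop filtering)."""
    body = "".join(rng.choice(list("ACGT"), size=3 * (length_codons - 1)))
    return "ATG" + body


def make_kozak_cds(
    strong_codons: Sequence[int],
    length_codons: int = 400,
    seed: int = 0,
) -> str:
    """Synthetic CDS with strong Kozak ATGs planted at the given codons.

    A stand-in for a real coding sequence: the background is random with
    all other in-frame ATGs and strong contexts scrubbed, then a
    gccRccATGG context is written at each requested codon, so a scan
    recovers exactly the planted sites.
    """
    rng = np.random.default_rng(seed)
    non_atg = [c for c in ("AAA", "CCA", "GAA", "CTT", "TCA", "GGA", "CAT", "TTC")]
    codons = ["ATG"] + [non_atg[rng.integers(len(non_atg))] for _ in range(length_codons - 1)]
    seq = list("".join(codons))
    for codon in strong_codons:
        nt = 3 * (codon - 1)  # 0-based index of the A
        if nt + 4 > len(seq) or nt < 6:
            raise ValueError(f"codon {codon} context does not fit in the CDS")
        seq[nt - 6 : nt] = list("GCCACC")   # -6..-1 with A at -3
        seq[nt : nt + 3] = list("ATG")
        seq[nt + 3] = "G"                   # +4
    return "".join(seq)
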
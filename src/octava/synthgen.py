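"""Synthetic OCT venoatrial-junction phantoms with known ground truth.

The generator emulates the contrast that separates left-atrial (LA) from
pulmonary-vein (PV) tissue in intensity OCT:

* **LA** A-lines show a thin, highly scattering endocardial layer — modelled
  as a reflectivity gain over the first ``endo_thickness`` of tissue — then a
  step down to the dimmer myocardium, both decaying as ``exp(-2 mu z)`` with
  a comparatively high attenuation coefficient ``mu_la``.
* **PV** A-lines are a single compartment with slower decay (lower
  ``mu_pv``), deeper penetration and a low-spatial-frequency reflectivity
  modulation that gives the vein wall its more heterogeneous texture.
* Fully developed **speckle** is modelled as i.i.d. unit-mean exponential
  multiplicative noise, the simplest model with the correct first moment.
* The tissue **surface** undulates smoothly so that surface detection and
  digital flattening are exercised.

Default attenuation coefficients are the sample averages reported for human
venoatrial junctions, 0.6042 mm^-1 (LA) and 0.5227 mm^-1 (PV). All
randomness flows through one seeded :class:`numpy.random.Generator`; the
same config and seed reproduce the volume bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

from .volume_io import Label, LabelMap, OCTVolume, write_hdf5, write_tiff

#: sample-average attenuation coefficients (mm^-1) used as defaults
MU_LA_DEFAULT = 0.6042
MU_PV_DEFAULT = 0.5227


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a synthetic venoatrial-junction volume.

    Lengths are mm; ``axial_spacing`` defaults to 3.67 um/px so that 64
    pixels span 235 um, the depth of one analysis patch.
    """

    grid_nx: int = 200
    grid_ny: int = 40
    depth_px: int = 128
    axial_spacing: float = 0.00367
    lateral_spacing_x: float = 0.00625
    lateral_spacing_y: float = 0.00625
    mu_la: float = MU_LA_DEFAULT
    mu_pv: float = MU_PV_DEFAULT
    endo_thickness_range: tuple[float, float] = (0.04, 0.08)
    endo_reflectivity_gain: float = 4.0
    myo_baseline: float = 1.0
    pv_texture_scale: float = 0.35
    surface_amp: float = 0.02
    transition_width: int = 20
    la_fraction: float = 0.70
    speckle: bool = True
    log_alpha: float = 100.0
    log_i_ref: float | None = 10.0  # display reference intensity; None -> volume max
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.axial_spacing, self.lateral_spacing_x, self.lateral_spacing_y) <= 0:
            raise ValueError("spacings must be strictly positive")
        if self.mu_la <= 0 or self.mu_pv <= 0:
            raise ValueError("attenuation coefficients must be positive")
        lo, hi = self.endo_thickness_range
        if not (0 < lo <= hi):
            raise ValueError("endo_thickness_range must be positive and ordered")
        if self.endo_reflectivity_gain <= 1:
            raise ValueError("endo_reflectivity_gain must exceed 1")
        if not (0 < self.la_fraction < 1):
            raise ValueError("la_fraction must lie in (0, 1)")
        if self.transition_width >= self.grid_nx:
            raise ValueError("transition_width must be smaller than grid_nx")
        if self.surface_amp < 0:
            raise ValueError("surface_amp must be non-negative")


@dataclass
class SyntheticVolume:
    """A generated phantom with ground truth attached."""

    linear_intensity: np.ndarray  # (depth, nx, ny) float32, non-negative
    display_uint8: np.ndarray  # (depth, nx, ny) uint8, log-compressed
    labels: LabelMap
    truth_mu: np.ndarray  # (nx, ny) mm^-1
    truth_endo_thickness: np.ndarray  # (nx, ny) mm, NaN outside LA influence
    truth_surface: np.ndarray  # (nx, ny) surface depth, pixels
    config: PhantomConfig

    def as_volume(self, domain: str = "linear", junction_id: str = "phantom-0") -> OCTVolume:
        """View the phantom as an :class:`OCTVolume` in either domain."""
        if domain == "linear":
            data, tag = self.linear_intensity, "linear"
        elif domain == "log8bit":
            data, tag = self.display_uint8, "log8bit"
        else:
            raise ValueError(f"unknown domain {domain!r}")
        return OCTVolume(
            intensity=data,
            axial_spacing=self.config.axial_spacing,
            lateral_spacing_x=self.config.lateral_spacing_x,
            lateral_spacing_y=self.config.lateral_spacing_y,
            junction_id=junction_id,
            domain_tag=tag,
        )


def log_compress(linear: np.ndarray, alpha: float = 100.0,
                 i_max: float | None = None) -> np.ndarray:
    """Map linear intensity to 8-bit display values.

    ``d = round(255 * log(1 + alpha*I) / log(1 + alpha*I_max))`` — a monotone
    transform, so pixel ordering within each A-line is preserved.
    """
    linear = np.asarray(linear, dtype=np.float64)
    if i_max is None:
        i_max = float(linear.max()) if linear.size else 1.0
    if i_max <= 0:
        return np.zeros(linear.shape, dtype=np.uint8)
    d = 255.0 * np.log1p(alpha * linear) / np.log1p(alpha * i_max)
    return np.rint(np.clip(d, 0, 255)).astype(np.uint8)


def generate_aline(
    tissue_class: Label | str,
    mu: float,
    depth_px: int,
    axial_spacing: float,
    rng: np.random.Generator,
    *,
    surface_px: int = 0,
    endo_thickness: float = 0.06,
    endo_reflectivity_gain: float = 4.0,
    myo_baseline: float = 1.0,
    pv_texture_scale: float = 0.35,
    speckle: bool = True,
) -> np.ndarray:
    """Generate one synthetic A-line (depth profile of linear intensity).

    LA: endocardial gain over ``[0, endo_thickness)`` then a step down to the
    myocardial baseline, all under ``exp(-2 mu z)``. PV: single-compartment
    Beer–Lambert decay with a smooth reflectivity modulation of amplitude
    ``pv_texture_scale``. Depth ``z`` is measured from the tissue surface;
    pixels above the surface are zero.
    """
    if isinstance(tissue_class, str):
        tissue_class = Label[tissue_class]
    if tissue_class not in (Label.LA, Label.PV):
        raise ValueError(f"tissue_class must be LA or PV, got {tissue_class!r}")
    if mu <= 0:
        raise ValueError("mu must be positive")

    n_tissue = depth_px - surface_px
    z = np.arange(n_tissue) * axial_spacing
    decay = np.exp(-2.0 * mu * z)
    if tissue_class == Label.LA:
        amplitude = np.where(z < endo_thickness, endo_reflectivity_gain, myo_baseline)
        profile = amplitude * decay
    else:
        # low-spatial-frequency modulation: random-phase long-period sinusoids
        n_waves = 3
        periods = rng.uniform(0.1, 0.4, size=n_waves)  # mm
        phases = rng.uniform(0, 2 * np.pi, size=n_waves)
        mod = np.zeros_like(z)
        for p, ph in zip(periods, phases):
            mod += np.sin(2 * np.pi * z / p + ph)
        mod *= pv_texture_scale / np.sqrt(n_waves)
        profile = np.clip(1.0 + mod, 0.05, None) * decay
    if speckle:
        profile = profile * rng.exponential(1.0, size=n_tissue)
    out = np.zeros(depth_px, dtype=np.float64)
    out[surface_px:] = profile
    return out


def _smooth_field(shape: tuple[int, int], sigma: tuple[float, float],
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-std smooth random field on an (nx, ny) grid."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_volume(config: PhantomConfig) -> SyntheticVolume:
    """Generate a full phantom volume from a config (deterministic in seed).

    The x-axis is partitioned into an LA band, a transition band in which LA
    and PV profiles are convexly blended (weight linear in x), and a PV band.
    The band boundary wanders with y (seeded jitter) so the en-face boundary
    is irregular, but every row has exactly ``transition_width`` transition
    A-lines. The surface height varies smoothly with amplitude
    ``surface_amp`` (mm).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nx, ny, depth = cfg.grid_nx, cfg.grid_ny, cfg.depth_px
    dz = cfg.axial_spacing

    # --- surface height (px), smooth in x and y
    if cfg.surface_amp > 0:
        surf_field = _smooth_field((nx, ny), sigma=(nx / 8, max(ny / 8, 1)), rng=rng)
        surf_px = np.rint((surf_field - surf_field.min()) / 2
                          * (2 * cfg.surface_amp / dz)).astype(np.int64)
        surf_px = np.clip(surf_px, 0, depth // 3)
    else:
        rng.standard_normal((nx, ny))  # keep stream layout stable
        surf_px = np.zeros((nx, ny), dtype=np.int64)

    # --- lateral partition: LA | transition | PV, boundary jittered per row
    n_tissue_x = nx - cfg.transition_width
    la_width = int(round(cfg.la_fraction * n_tissue_x))
    la_width = min(max(la_width, 1), n_tissue_x - 1)
    jitter_amp = max(2, nx // 32)
    jitter = np.rint(jitter_amp * _smooth_field((ny, 1), sigma=(max(ny / 6, 1), 1), rng=rng)
                     ).astype(np.int64)[:, 0]
    la_end = np.clip(la_width + jitter, 1, nx - cfg.transition_width - 1)  # per y

    xs = np.arange(nx)[:, None]  # (nx, 1)
    la_end_row = la_end[None, :]  # (1, ny)
    in_la = xs < la_end_row
    in_trans = (xs >= la_end_row) & (xs < la_end_row + cfg.transition_width)
    labels = np.where(in_la, int(Label.LA),
                      np.where(in_trans, int(Label.TRANSITION), int(Label.PV))).astype(np.int8)
    # PV blend weight: 0 in LA, linear ramp across the transition, 1 in PV
    if cfg.transition_width > 0:
        w = np.clip((xs - la_end_row + 1) / (cfg.transition_width + 1), 0.0, 1.0)
    else:
        w = (~in_la).astype(np.float64)

    # --- per-A-line ground truth
    t_lo, t_hi = cfg.endo_thickness_range
    thick_field = _smooth_field((nx, ny), sigma=(nx / 10, max(ny / 10, 1)), rng=rng)
    tf = (thick_field - thick_field.min())
    tf /= tf.max() if tf.max() > 0 else 1.0
    endo_thickness = t_lo + tf * (t_hi - t_lo)  # (nx, ny) mm
    mu = (1.0 - w) * cfg.mu_la + w * cfg.mu_pv  # blended truth mu

    # --- profiles on a common depth-from-surface axis, then shift to surface
    z = np.arange(depth)[:, None, None] * dz  # (depth, 1, 1)
    la_amp = np.where(z < endo_thickness[None, :, :],
                      cfg.endo_reflectivity_gain, cfg.myo_baseline)
    la_profile = la_amp * np.exp(-2.0 * cfg.mu_la * z)

    # PV texture: smooth 3-D modulation, low spatial frequency in depth and x
    tex_noise = rng.standard_normal((depth, nx, ny))
    tex = ndimage.gaussian_filter(tex_noise, sigma=(12, 8, 2), mode="wrap")
    tsd = tex.std()
    tex = tex / tsd if tsd > 0 else tex
    pv_profile = np.clip(1.0 + cfg.pv_texture_scale * tex, 0.05, None) \
        * np.exp(-2.0 * cfg.mu_pv * z)

    profile = (1.0 - w)[None, :, :] * la_profile + w[None, :, :] * pv_profile

    if cfg.speckle:
        profile = profile * rng.exponential(1.0, size=profile.shape)

    # shift each A-line down by its surface height (zeros above the surface)
    idx = np.arange(depth)[:, None, None] - surf_px[None, :, :]
    above = idx < 0
    idx = np.clip(idx, 0, depth - 1)
    linear = np.take_along_axis(profile, idx, axis=0)
    linear[above] = 0.0
    linear = linear.astype(np.float32)

    display = log_compress(linear, alpha=cfg.log_alpha, i_max=cfg.log_i_ref)
    return SyntheticVolume(
        linear_intensity=linear,
        display_uint8=display,
        labels=LabelMap(labels),
        truth_mu=mu * np.ones((nx, ny)) if np.ndim(mu) != 2 else np.broadcast_to(mu, (nx, ny)).copy(),
        truth_endo_thickness=np.where(w < 1.0, endo_thickness, np.nan),
        truth_surface=surf_px,
        config=cfg,
    )


def generate_junction_set(
    n_junctions: int,
    base_config: PhantomConfig,
    seed: int,
    *,
    mu_jitter_sd: float = 0.03,
    gain_jitter_sigma: float = 0.20,
    texture_jitter_sigma: float = 0.25,
    brightness_jitter_sigma: float = 0.25,
    la_fraction_sd: float = 0.05,
) -> list[tuple[str, SyntheticVolume]]:
    """Generate a cohort of phantom junctions for a grouped-CV study.

    Each junction gets its own child seed plus specimen-level jitter of the
    optical parameters, emulating the donor-to-donor variability (pathology,
    tissue remodeling, dissection extent, acquisition brightness) that makes
    junction-grouped cross-validation a non-trivial generalization test:

    * both attenuation coefficients jittered (sd ``mu_jitter_sd`` mm^-1,
      LA > PV ordering preserved),
    * endocardial reflectivity gain and PV texture amplitude jittered
      log-normally,
    * a log-normal per-acquisition brightness factor, so absolute intensity
      is not a reliable class cue (as in real multi-acquisition data),
    * the LA fraction of the grid jittered (dissections retain variable
      amounts of vein).
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_junctions)
    out = []
    for j, child in enumerate(children):
        jrng = np.random.default_rng(child)
        mu_la = base_config.mu_la + mu_jitter_sd * jrng.standard_normal()
        mu_pv = base_config.mu_pv + mu_jitter_sd * jrng.standard_normal()
        mu_la = max(mu_la, 0.05)
        mu_pv = float(np.clip(mu_pv, 0.05, mu_la - 0.01))  # keep LA > PV ordering
        gain = float(base_config.endo_reflectivity_gain
                     * np.exp(gain_jitter_sigma * jrng.standard_normal()))
        gain = max(gain, 1.2)
        texture = float(base_config.pv_texture_scale
                        * np.exp(texture_jitter_sigma * jrng.standard_normal()))
        brightness = float(np.exp(brightness_jitter_sigma * jrng.standard_normal()))
        la_frac = float(np.clip(base_config.la_fraction
                                + la_fraction_sd * jrng.standard_normal(), 0.5, 0.85))
        cfg = replace(base_config, mu_la=float(mu_la), mu_pv=mu_pv,
                      endo_reflectivity_gain=gain, pv_texture_scale=texture,
                      la_fraction=la_frac,
                      seed=int(jrng.integers(0, 2**31 - 1)))
        phantom = generate_volume(cfg)
        # brightness scales the whole acquisition; the 8-bit display uses a
        # fixed reference intensity, so the factor carries into both domains
        phantom.linear_intensity = phantom.linear_intensity * np.float32(brightness)
        phantom.display_uint8 = log_compress(phantom.linear_intensity,
                                             alpha=cfg.log_alpha, i_max=cfg.log_i_ref)
        out.append((f"junction-{j:02d}", phantom))
    return out


def save_phantom(path: str | Path, phantom: SyntheticVolume,
                 junction_id: str = "phantom-0", tiff_path: str | Path | None = None) -> None:
    """Write the HDF5 sidecar (linear + labels + truth + config) and
    optionally a display-domain multi-page TIFF."""
    vol = phantom.as_volume("linear", junction_id)
    write_hdf5(path, vol, phantom.labels)
    with h5py.File(path, "a") as f:
        f.create_dataset("display_uint8", data=phantom.display_uint8)
        f.create_dataset("truth/mu", data=phantom.truth_mu)
        f.create_dataset("truth/endo_thickness", data=phantom.truth_endo_thickness)
        f.create_dataset("truth/surface", data=phantom.truth_surface)
        f.attrs["config"] = json.dumps(asdict(phantom.config))
    if tiff_path is not None:
        write_tiff(tiff_path, phantom.as_volume("log8bit", junction_id))


def load_phantom(path: str | Path) -> SyntheticVolume:
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config"])
        cfg_dict["endo_thickness_range"] = tuple(cfg_dict["endo_thickness_range"])
        return SyntheticVolume(
            linear_intensity=f["intensity"][...],
            display_uint8=f["display_uint8"][...],
            labels=LabelMap(f["labels"][...]),
            truth_mu=f["truth/mu"][...],
            truth_endo_thickness=f["truth/endo_thickness"][...],
            truth_surface=f["truth/surface"][...],
            config=PhantomConfig(**cfg_dict),
        )
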
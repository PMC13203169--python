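"""Synthetic 3-D shoulder phantoms with known masks, grades and implant labels.

Each phantom contains two bone-like objects on a voxel grid: an ellipsoidal
humeral head carrying osteophyte-like surface bumps, and a curved scapular
plate (a spherical-shell cap, glenoid-fashion) facing it across a
configurable joint-space gap. Four categorical labels are generated:

* ``os_grade`` — osteophyte severity, three grades by protrusion height
  (<3, 3-7, >7 mm; defaults 1.5 / 5 / 9 mm),
* ``js_grade`` — joint-space condition (physiological / narrowed /
  non-detectable; default gaps 4 / 1.5 / 0 mm),
* ``hsa_grade`` — humeroscapular alignment (concentric vs eccentric; the
  eccentric head is displaced superiorly, default 5 mm),
* ``implant`` — reverse (0) iff the joint is eccentric, collapsed or carries
  severe osteophytes, else anatomical (1), optionally flipped with
  probability ``label_noise_p``.

A simulated rater panel draws per-case implant votes from per-rater
sensitivity/bias profiles, mirroring a surgeon cohort reading only bone
morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelVolume, VoxelVolume

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "RaterProfile",
    "generate_phantom",
    "generate_cohort",
    "generate_rater_panel",
    "save_panel_csv",
    "load_panel_csv",
]

_CUP_HALF_ANGLE_DEG = 55.0
_BUMP_CONE_COS = 0.6  # bumps live on the lateral hemisphere, away from the cup


@dataclass
class PhantomConfig:
    """Generation parameters for one phantom case."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    os_grade: int = 0
    js_grade: int = 0
    hsa_grade: int = 0
    noise_sd: float = 25.0
    label_noise_p: float = 0.0
    seed: int = 0
    # geometry knobs (mm)
    gap_mm: tuple[float, float, float] = (4.0, 1.5, 0.0)
    offset_mm: tuple[float, float] = (0.0, 5.0)
    protrusion_mm: tuple[float, float, float] = (1.5, 5.0, 9.0)
    head_radius_mm: float | None = None
    cup_thickness_mm: float = 3.0
    n_bumps: int = 6

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.grid_shape) != 3 or any(g < 16 for g in self.grid_shape):
            raise ValueError(f"grid_shape components must be >= 16, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.os_grade not in (0, 1, 2):
            raise ValueError(f"os_grade must be in {{0,1,2}}, got {self.os_grade}")
        if self.js_grade not in (0, 1, 2):
            raise ValueError(f"js_grade must be in {{0,1,2}}, got {self.js_grade}")
        if self.hsa_grade not in (0, 1):
            raise ValueError(f"hsa_grade must be in {{0,1}}, got {self.hsa_grade}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.label_noise_p <= 1.0:
            raise ValueError("label_noise_p must lie in [0, 1]")
        if self.gap_mm[2] != 0.0:
            raise ValueError("gap for js_grade 2 (non-detectable) must be exactly 0")
        if self.offset_mm[0] != 0.0:
            raise ValueError("offset for hsa_grade 0 (concentric) must be exactly 0")


@dataclass
class RaterProfile:
    """Response model of one simulated rater on the implant-type question."""

    sensitivity_anatomical: float = 0.75
    sensitivity_reverse: float = 0.75
    bias_reverse: float = 0.0

    def __post_init__(self):
        for name in ("sensitivity_anatomical", "sensitivity_reverse", "bias_reverse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class PhantomCase:
    image: VoxelVolume
    labels: LabelVolume
    os_grade: int
    js_grade: int
    hsa_grade: int
    implant: int  # 0 reverse, 1 anatomical
    config: PhantomConfig = field(repr=False)


def implant_rule(os_grade: int, js_grade: int, hsa_grade: int) -> int:
    """Deterministic implant surrogate: reverse (0) iff eccentric alignment,
    collapsed joint space, or severe osteophytes; anatomical (1) otherwise."""
    return 0 if (hsa_grade == 1 or js_grade == 2 or os_grade == 2) else 1


def _geometry(cfg: PhantomConfig):
    extent = np.array(cfg.grid_shape) * np.array(cfg.spacing)
    r_head = cfg.head_radius_mm if cfg.head_radius_mm is not None else 0.19 * extent.min()
    gap = cfg.gap_mm[cfg.js_grade]
    offset = cfg.offset_mm[cfg.hsa_grade]
    bump = cfg.protrusion_mm[cfg.os_grade]
    r_in = r_head + gap
    r_out = r_in + cfg.cup_thickness_mm
    # containment check per axis: cup extent vs head + worst-case bump reach
    margin = max(cfg.spacing)
    sin_bump = float(np.sqrt(1.0 - _BUMP_CONE_COS**2))
    need_x = max(r_out, 1.05 * r_head + bump) + margin
    need_yz = max(r_out * np.sin(np.radians(_CUP_HALF_ANGLE_DEG)),
                  offset + sin_bump * 1.05 * r_head + bump) + margin
    half = extent / 2.0
    if need_x > half[0] or need_yz > half[1] or need_yz > half[2]:
        raise ValueError(
            "grid too small to contain both objects at the requested spacing: "
            f"need half-extents ~({need_x:.1f}, {need_yz:.1f}, {need_yz:.1f}) mm, "
            f"have {tuple(np.round(half, 1))} mm"
        )
    return extent, r_head, gap, offset, bump, r_in, r_out


_SIX = ndimage.generate_binary_structure(3, 1)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_SIX)
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def generate_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate one phantom; deterministic given ``config.seed``."""
    cfg = config
    extent, r_head, gap, offset, bump_h, r_in, r_out = _geometry(cfg)
    rng = np.random.default_rng(cfg.seed)

    sp = np.array(cfg.spacing)
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(cfg.grid_shape, sp)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    c0 = extent / 2.0  # socket centre
    ch = c0 + np.array([0.0, 0.0, offset])  # head centre, superior shift if eccentric

    # humeral head: mildly anisotropic ellipsoid
    ax = np.array([r_head, 0.95 * r_head, 1.05 * r_head])
    head = (((X - ch[0]) / ax[0]) ** 2 + ((Y - ch[1]) / ax[1]) ** 2
            + ((Z - ch[2]) / ax[2]) ** 2) <= 1.0

    # osteophyte bumps: spheres of radius == protrusion height, centred on the
    # lateral head surface (cone v.x >= _BUMP_CONE_COS, away from the cup).
    # Directions are drawn before grade use, so a fixed seed places the same
    # bumps for every grade.
    dirs = []
    while len(dirs) < cfg.n_bumps:
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        if v[0] >= _BUMP_CONE_COS:
            dirs.append(v)
    humerus = head.copy()
    for v in dirs:
        # radius of the ellipsoid along v
        rv = 1.0 / np.sqrt((v[0] / ax[0]) ** 2 + (v[1] / ax[1]) ** 2 + (v[2] / ax[2]) ** 2)
        bc = ch + v * rv
        bump = ((X - bc[0]) ** 2 + (Y - bc[1]) ** 2 + (Z - bc[2]) ** 2) <= bump_h**2
        humerus |= bump

    # scapular plate: spherical-shell cap around the socket centre, opening
    # toward -x, gap-controlled inner radius
    r2 = (X - c0[0]) ** 2 + (Y - c0[1]) ** 2 + (Z - c0[2]) ** 2
    r = np.sqrt(r2)
    shell = (r >= r_in) & (r <= r_out)
    with np.errstate(invalid="ignore", divide="ignore"):
        cone = np.where(r > 0, (c0[0] - X) / np.maximum(r, 1e-9), 0.0) >= np.cos(
            np.radians(_CUP_HALF_ANGLE_DEG)
        )
    scapula = shell & cone & ~humerus
    # collapsed/eccentric joints can shave off stray shell voxels; keep each
    # bone a single 6-connected object
    humerus = _largest_component(humerus)
    scapula = _largest_component(scapula)

    labels = np.zeros(cfg.grid_shape, dtype=np.int16)
    labels[scapula] = 2
    labels[humerus] = 1

    # intensity: low background plateau, trabecular bone plateau, bright
    # 1-voxel cortical rim, additive Gaussian noise
    image = np.zeros(cfg.grid_shape, dtype=np.float64)
    bone = humerus | scapula
    interior = ndimage.binary_erosion(bone)
    image[bone] = 1200.0
    image[interior] = 800.0
    if cfg.noise_sd > 0:
        image += rng.normal(0.0, cfg.noise_sd, size=cfg.grid_shape)

    implant = implant_rule(cfg.os_grade, cfg.js_grade, cfg.hsa_grade)
    if cfg.label_noise_p > 0 and rng.random() < cfg.label_noise_p:
        implant = 1 - implant

    return PhantomCase(
        image=VoxelVolume(image, cfg.spacing),
        labels=LabelVolume(labels, cfg.spacing),
        os_grade=cfg.os_grade,
        js_grade=cfg.js_grade,
        hsa_grade=cfg.hsa_grade,
        implant=implant,
        config=cfg,
    )


def generate_cohort(n: int, seed: int, balance_implant: bool = False,
                    **config_kwargs) -> list[PhantomCase]:
    """Generate ``n`` phantoms with grades drawn uniformly at random.

    With ``balance_implant`` the cohort alternates implant targets so both
    prosthesis types appear in equal proportion (grades are resampled until
    the deterministic rule hits the target), mirroring a balanced test
    design; otherwise uniform grades leave reverse joints in the majority.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        while True:
            os_g, js_g = int(rng.integers(3)), int(rng.integers(3))
            hsa_g = int(rng.integers(2))
            if not balance_implant or implant_rule(os_g, js_g, hsa_g) == i % 2:
                break
        cfg = PhantomConfig(
            os_grade=os_g, js_grade=js_g, hsa_grade=hsa_g,
            seed=int(rng.integers(2**31 - 1)),
            **config_kwargs,
        )
        cases.append(generate_phantom(cfg))
    return cases


def generate_rater_panel(
    cases: list[PhantomCase] | list[int],
    profiles: list[RaterProfile],
    seed: int,
) -> pd.DataFrame:
    """Simulate per-rater implant votes for each case.

    ``cases`` may be PhantomCase objects or bare implant labels (0/1).
    Returns a DataFrame with a ``case_id`` column and one 0/1 column per
    rater (``rater_01`` ...). A rater answers correctly with the class
    sensitivity of the true label; with probability ``bias_reverse`` the
    response is overridden toward reverse.
    """
    if len(cases) < 1:
        raise ValueError("need at least 1 case")
    if len(profiles) < 2:
        raise ValueError("need at least 2 raters")
    truths = np.array([c.implant if isinstance(c, PhantomCase) else int(c) for c in cases])
    rng = np.random.default_rng(seed)
    out = {"case_id": [f"case_{i:04d}" for i in range(len(cases))]}
    for j, prof in enumerate(profiles):
        votes = np.empty(len(cases), dtype=np.int64)
        for i, t in enumerate(truths):
            sens = prof.sensitivity_anatomical if t == 1 else prof.sensitivity_reverse
            resp = t if rng.random() < sens else 1 - t
            if prof.bias_reverse > 0 and rng.random() < prof.bias_reverse:
                resp = 0
            votes[i] = resp
        out[f"rater_{j + 1:02d}"] = votes
    return pd.DataFrame(out)


def save_panel_csv(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


def load_panel_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
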
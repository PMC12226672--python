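"""Synthetic multi-wavelength phantom cohorts with plantable sex and disease features.

Real photoacoustic cohorts of peripheral-artery-disease (PAD) patients are not
publicly deposited, so the audit pipeline ships with a generator that emulates
the *statistical* situation it is designed to probe: binary sex and disease
attributes whose image correlates live in distinct feature families.

* Sex manifests superficially — a bright band at the top of the image whose
  thickness (think skin/subcutaneous-fat layering) shifts with sex.
* Disease manifests as vessel-like elliptical blobs deeper in the tissue whose
  number and contrast are reduced in diseased subjects (reduced perfusion).
* An ``overlap`` dial adds a shared mid-depth component whose amplitude
  responds to *both* labels, making the two encodings partially transferable —
  the mechanism that lets shortcut learning be switched on and off.

Three channels emulate a three-wavelength acquisition; channels differ only by
fixed absorption-like weights.  None of this is a physical simulation of
photoacoustic wave propagation — the feature families are statistical
stand-ins, not claims about tissue optics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "Subject",
    "SITE_PROFILES",
    "generate_subject",
    "generate_pool",
    "save_cohort",
    "load_cohort",
    "cohort_metadata",
]

#: Baseline texture statistics per body site. Sites differ only in baseline
#: intensity and texture, never in how the labels manifest, so a classifier
#: trained on one site can in principle generalize to the others.
SITE_PROFILES = {
    "calf": {"base": 0.55, "texture_amp": 0.12, "texture_cell": 8},
    "forearm": {"base": 0.45, "texture_amp": 0.09, "texture_cell": 4},
    "neck": {"base": 0.65, "texture_amp": 0.15, "texture_cell": 16},
}

#: Per-channel multipliers emulating wavelength-dependent absorption for the
#: background / band and for blood-filled vessels respectively.
_CHANNEL_BG = np.array([1.00, 0.92, 0.85])
_CHANNEL_VESSEL = np.array([1.10, 1.00, 0.90])

_SEXES = ("F", "M")
_DISEASES = ("H", "D")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the phantom generator.

    ``sex_effect`` and ``disease_effect`` are dimensionless scales of the two
    label pathways; at 0 the corresponding labels leave the image distribution
    untouched. ``overlap`` in [0, 1] controls how much image structure the two
    feature families share. ``noise_sd`` is the i.i.d. pixel-noise standard
    deviation in intensity units.
    """

    image_height: int = 64
    image_width: int = 64
    n_channels: int = 3
    sex_effect: float = 1.0
    disease_effect: float = 1.0
    overlap: float = 0.5
    noise_sd: float = 0.1
    site_profile: str = "calf"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.sex_effect < 0 or self.disease_effect < 0:
            raise ValueError("effect sizes must be >= 0")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.site_profile not in SITE_PROFILES:
            raise ValueError(f"unknown site_profile {self.site_profile!r}")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Subject:
    """One individual: immutable labels plus a (C, H, W) intensity image."""

    subject_id: str
    sex: str
    disease: str
    image: np.ndarray = field(repr=False)
    site: str = "calf"

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.disease not in _DISEASES:
            raise ValueError(f"disease must be one of {_DISEASES}, got {self.disease!r}")
        self.image.setflags(write=False)


def _channel_weights(base: np.ndarray, n_channels: int) -> np.ndarray:
    # repeat/trim the three-wavelength weights for non-default channel counts
    reps = int(np.ceil(n_channels / base.size))
    return np.tile(base, reps)[:n_channels]


def generate_subject(
    sex: str,
    disease: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> Subject:
    """Draw one phantom image for the given sex/disease labels.

    The image is baseline site texture + a superficial sex-linked band +
    deeper disease-linked vessel blobs + a shared component responding to both
    labels (weighted by ``config.overlap``) + i.i.d. Gaussian noise, clipped to
    non-negative intensities. Deterministic given ``rng``'s state.
    """
    if sex not in _SEXES:
        raise ValueError(f"sex must be one of {_SEXES}, got {sex!r}")
    if disease not in _DISEASES:
        raise ValueError(f"disease must be one of {_DISEASES}, got {disease!r}")

    H, W, C = config.image_height, config.image_width, config.n_channels
    site = SITE_PROFILES[config.site_profile]
    s = 1.0 if sex == "F" else -1.0
    d = 1.0 if disease == "D" else -1.0

    bg_w = _channel_weights(_CHANNEL_BG, C)
    vessel_w = _channel_weights(_CHANNEL_VESSEL, C)

    # --- baseline: flat site intensity + smooth low-frequency texture -------
    cell = max(1, int(site["texture_cell"] * H / 64))
    gh, gw = -(-H // cell), -(-W // cell)
    coarse = rng.normal(0.0, 1.0, size=(gh, gw))
    texture = np.kron(coarse, np.ones((cell, cell)))[:H, :W] * site["texture_amp"]
    rows = np.arange(H, dtype=float)

    img = site["base"] * bg_w[:, None, None] * np.ones((C, H, W))
    img += texture[None, :, :] * bg_w[:, None, None]

    # --- sex pathway: thickness of the superficial bright band --------------
    # Per-sex mean shift of +-(H/32)*sex_effect rows around a base thickness
    # of H/8, with subject jitter of sd H/32 so classes overlap.
    t_base = H / 8.0
    t = t_base + s * config.sex_effect * (H / 32.0) + rng.normal(0.0, H / 18.0)
    t = float(np.clip(t, 1.0, H / 3.0))
    band_amp = 0.35 + rng.normal(0.0, 0.02)
    # soft lower edge (one-pixel sigmoid) so thickness varies sub-pixel smoothly
    band_profile = 1.0 / (1.0 + np.exp(-(t - rows)))
    img += band_amp * band_profile[None, :, None] * bg_w[:, None, None]

    # --- disease pathway: count & contrast of vessel-like blobs -------------
    lam = 5.0 * max(0.0, 1.0 - 0.20 * d * config.disease_effect)
    n_vessels = max(0, int(round(lam + rng.normal(0.0, 0.8))))
    vessel_amp = max(0.0, 0.5 * (1.0 - 0.25 * d * config.disease_effect) + rng.normal(0.0, 0.04))
    size_mod = max(0.25, 1.0 - 0.10 * d * config.disease_effect)
    r_lo, r_hi = H / 4.0, H - 2.0
    cols = np.arange(W, dtype=float)
    for _ in range(n_vessels):
        r0 = rng.uniform(r_lo, r_hi)
        c0 = rng.uniform(1.0, W - 1.0)
        ar = rng.uniform(2.0, 4.0) * size_mod * H / 64.0
        ac = rng.uniform(2.0, 4.0) * size_mod * W / 64.0
        blob = np.exp(-(((rows[:, None] - r0) / ar) ** 2 + ((cols[None, :] - c0) / ac) ** 2))
        img += vessel_amp * blob[None, :, :] * vessel_w[:, None, None]

    # --- shared component: responds to BOTH labels, gated by overlap --------
    # A mid-depth horizontal stripe; its amplitude mixes the two label signs,
    # which is what makes the sex and disease encodings transferable.
    shared_amp = config.overlap * 0.05 * (
        s * config.sex_effect + d * config.disease_effect
    ) + config.overlap * rng.normal(0.0, 0.01)
    stripe = np.exp(-0.5 * ((rows - 0.42 * H) / (H / 12.0)) ** 2)
    img += shared_amp * stripe[None, :, None] * bg_w[:, None, None]

    # --- pixel noise, non-negativity ----------------------------------------
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=(C, H, W))
    img = np.clip(img, 0.0, None).astype(np.float32)

    return Subject(subject_id="", sex=sex, disease=disease, image=img, site=config.site_profile)


def generate_pool(
    counts,
    config: GeneratorConfig,
    seed: int | None = None,
    id_prefix: str = "S",
) -> list[Subject]:
    """Generate exactly ``counts`` subjects per sex-by-disease stratum.

    ``counts`` is a :class:`patshortcut.sampling.StratumCounts` or anything
    with fh/fd/mh/md attributes. One root seed sequence is split per subject
    by counter, so subject ``i`` is reproducible regardless of generation
    order. ``seed`` defaults to ``config.seed``.
    """
    for name in ("fh", "fd", "mh", "md"):
        if getattr(counts, name) < 0:
            raise ValueError("stratum counts must be non-negative")
    strata = [
        ("F", "H", counts.fh),
        ("F", "D", counts.fd),
        ("M", "H", counts.mh),
        ("M", "D", counts.md),
    ]
    total = sum(n for _, _, n in strata)
    root = np.random.SeedSequence([config.seed if seed is None else int(seed), 0x5EED])
    children = root.spawn(total)
    subjects: list[Subject] = []
    i = 0
    for sex, disease, n in strata:
        for _ in range(n):
            rng = np.random.default_rng(children[i])
            subj = generate_subject(sex, disease, config, rng)
            subjects.append(
                dataclasses.replace(subj, subject_id=f"{id_prefix}{i:04d}")
            )
            i += 1
    return subjects


def cohort_metadata(subjects: Sequence[Subject]) -> pd.DataFrame:
    """Per-subject metadata table (subject_id, sex, disease, site)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "sex": [s.sex for s in subjects],
            "disease": [s.disease for s in subjects],
            "site": [s.site for s in subjects],
        }
    )


def save_cohort(subjects: Sequence[Subject], images_path, meta_path, split=None) -> None:
    """Write a cohort as a compressed array archive plus a CSV metadata table.

    ``split``, if given, maps subject_id -> split tag and is stored as an
    extra CSV column.
    """
    images_path, meta_path = Path(images_path), Path(meta_path)
    arrays = {s.subject_id: s.image for s in subjects}
    np.savez_compressed(images_path, **arrays)
    meta = cohort_metadata(subjects)
    if split is not None:
        meta["split"] = [split[sid] for sid in meta["subject_id"]]
    meta.to_csv(meta_path, index=False)


def load_cohort(images_path, meta_path) -> list[Subject]:
    """Inverse of :func:`save_cohort` (the split column, if any, is ignored)."""
    meta = pd.read_csv(meta_path)
    with np.load(Path(images_path)) as data:
        return [
            Subject(
                subject_id=row.subject_id,
                sex=row.sex,
                disease=row.disease,
                image=np.array(data[row.subject_id]),
                site=row.site,
            )
            for row in meta.itertuples()
        ]
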
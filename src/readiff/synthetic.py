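"""Synthetic screening cohort: lumpy-background views plus reader panels.

Real screening mammograms and reader data cannot be redistributed, so the
package ships a generator in the clustered-lumpy-background tradition of
medical image perception research.  Each case has four views (L/R x CC/MLO)
built as a sum of Gaussian blobs inside a half-disc breast silhouette on a
dark background; MLO views additionally carry a bright triangular pectoral
wedge in the chest-wall corner.  Cancer cases contain one Gaussian lesion
at a recorded location in the CC and MLO views of one side.

Every case carries a latent difficulty d_c — the cohort-standardized blob
width (all blobs in a case share one width, so coarse-textured cases are
*difficult*).  A simulated reader r errs on case c with probability

    sigmoid(alpha + beta * d_c + b_r),      b_r ~ Normal(0, reader_bias_sd)

so beta = 0 gives texture-independent errors and large beta couples errors
tightly to texture, which downstream feature extraction + modelling must
recover.  All randomness flows from ``config.seed`` through named
``numpy.random.SeedSequence`` substreams (per-case image streams, one
reader-panel stream), so output is bit-reproducible across platforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, InputError

__all__ = [
    "SyntheticConfig", "CaseRecord", "ReaderResponse", "GroundTruthDifficulty",
    "generate_case", "generate_cohort", "simulate_reader_panel",
    "write_cohort", "responses_frame", "truth_frame",
]

VIEWS = ("LCC", "LMLO", "RCC", "RMLO")

# substream tags; never reuse across purposes
_STREAM_CASE = 0
_STREAM_READERS = 1


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the simulator (see docs/methods.md for rationale)."""

    n_normal: int = 40
    n_cancer: int = 20
    image_size: int = 256
    blob_count_range: tuple[int, int] = (60, 100)
    blob_sigma_range: tuple[float, float] = (2.0, 8.0)
    blob_amplitude_range: tuple[float, float] = (0.5, 1.0)
    lesion_contrast: float = 0.8
    lesion_sigma: float = 5.0
    n_readers: int = 20
    error_link_intercept: float = -0.85  # logit(~0.3)
    error_link_slope: float = 2.0        # beta: texture -> error coupling
    reader_bias_sd: float = 0.5
    localization_error_fraction: float = 0.3
    localization_radius: float | None = None  # default image_size / 8
    wedge_angle_deg: float = 25.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_normal < 1 or self.n_cancer < 1 or self.n_readers < 1:
            raise ConfigurationError("n_normal, n_cancer and n_readers must be >= 1")
        if self.image_size < 64:
            raise ConfigurationError("image_size must be >= 64")
        for name in ("blob_count_range", "blob_sigma_range", "blob_amplitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigurationError(f"{name} must be a positive (lo, hi) interval")

    @property
    def n_cases(self) -> int:
        return self.n_normal + self.n_cancer

    @property
    def loc_radius(self) -> float:
        return self.localization_radius if self.localization_radius is not None else self.image_size / 8


@dataclass
class CaseRecord:
    case_id: str
    cancer: bool
    views: dict[str, np.ndarray]
    lesion_side: str | None = None              # "L" | "R"
    lesion_coords: dict[str, tuple[int, int]] = field(default_factory=dict)  # view -> (row, col)
    mean_blob_sigma: float = 0.0
    n_blobs: int = 0
    silhouettes: dict[str, np.ndarray] = field(default_factory=dict)
    wedges: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class GroundTruthDifficulty:
    case_id: str
    latent_difficulty: float                    # d_c, standardized over the cohort
    expected_error_prob: dict[str, float]       # basis -> probability at b_r = 0


@dataclass(frozen=True)
class ReaderResponse:
    reader_id: str
    case_id: str
    rating: int
    view: str | None = None
    x: float | None = None   # column
    y: float | None = None   # row


def _case_rng(config: SyntheticConfig, case_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_CASE, case_index)))


def _silhouette(size: int) -> np.ndarray:
    """Half-disc breast silhouette, chest wall on the left edge."""
    r = np.arange(size)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    cy, radius = size / 2, 0.46 * size
    return (rr - cy) ** 2 + cc ** 2 <= radius ** 2


def _wedge(size: int, angle_deg: float) -> np.ndarray:
    """Pectoral triangle in the top-left corner for MLO views."""
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    depth = 0.35 * size
    slope = np.tan(np.deg2rad(angle_deg))  # cols per row, measured from vertical
    return cc < (depth - rr) * slope


def _render_view(rng, config, silhouette, sigma_c, with_wedge, lesion_rc):
    size = config.image_size
    img = np.zeros((size, size))
    n_blobs = int(rng.integers(config.blob_count_range[0], config.blob_count_range[1] + 1))
    in_rows, in_cols = np.nonzero(silhouette)
    pick = rng.integers(0, len(in_rows), size=n_blobs)
    amps = rng.uniform(*config.blob_amplitude_range, size=n_blobs)
    half = int(np.ceil(4 * sigma_c))
    ax = np.arange(-half, half + 1)
    bump = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma_c ** 2))
    for k in range(n_blobs):
        r0, c0 = int(in_rows[pick[k]]), int(in_cols[pick[k]])
        rlo, rhi = max(0, r0 - half), min(size, r0 + half + 1)
        clo, chi = max(0, c0 - half), min(size, c0 + half + 1)
        img[rlo:rhi, clo:chi] += amps[k] * bump[
            rlo - (r0 - half) : bump.shape[0] - ((r0 + half + 1) - rhi),
            clo - (c0 - half) : bump.shape[1] - ((c0 + half + 1) - chi),
        ]
    img += 1.0  # tissue floor: breast clearly brighter than background, as on film
    img *= silhouette
    wedge = np.zeros_like(silhouette)
    if with_wedge:
        wedge = _wedge(size, config.wedge_angle_deg) & silhouette
        img[wedge] += 1.5
    if lesion_rc is not None:
        r0, c0 = lesion_rc
        ls = config.lesion_sigma
        lh = int(np.ceil(4 * ls))
        ax = np.arange(-lh, lh + 1)
        lb = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * ls ** 2))
        rlo, rhi = max(0, r0 - lh), min(size, r0 + lh + 1)
        clo, chi = max(0, c0 - lh), min(size, c0 + lh + 1)
        img[rlo:rhi, clo:chi] += config.lesion_contrast * lb[
            rlo - (r0 - lh) : lb.shape[0] - ((r0 + lh + 1) - rhi),
            clo - (c0 - lh) : lb.shape[1] - ((c0 + lh + 1) - chi),
        ] * silhouette[rlo:rhi, clo:chi]
    img += rng.normal(0.0, config.noise_sd, size=img.shape)
    img[~silhouette & ~wedge] = np.maximum(img[~silhouette & ~wedge], 0.0)
    return np.clip(img, 0.0, None), n_blobs, wedge


def generate_case(config: SyntheticConfig, case_index: int) -> CaseRecord:
    """Deterministically build one four-view case from (seed, case_index)."""
    if case_index < 0 or case_index >= config.n_cases:
        raise InputError(f"case_index {case_index} out of range")
    rng = _case_rng(config, case_index)
    cancer = case_index >= config.n_normal
    size = config.image_size
    silhouette = _silhouette(size)
    sigma_c = float(rng.uniform(*config.blob_sigma_range))

    lesion_side = None
    lesion_rc = None
    if cancer:
        lesion_side = "L" if rng.random() < 0.5 else "R"
        # keep the lesion well inside the silhouette (margin = loc radius + lesion size)
        margin = int(config.loc_radius + 3 * config.lesion_sigma)
        in_rows, in_cols = np.nonzero(silhouette)
        cy, radius = size / 2, 0.46 * size
        dist_ok = ((in_rows - cy) ** 2 + in_cols ** 2) <= (radius - margin) ** 2
        cand = np.nonzero(dist_ok & (in_cols > margin // 2))[0]
        if cand.size == 0:
            raise ConfigurationError("image too small for lesion placement margin")
        k = int(rng.integers(0, cand.size))
        lesion_rc = (int(in_rows[cand[k]]), int(in_cols[cand[k]]))

    views, silhouettes, wedges, lesion_coords = {}, {}, {}, {}
    n_blobs_total = 0
    for view in VIEWS:
        side, proj = view[0], view[1:]
        this_lesion = lesion_rc if (cancer and side == lesion_side) else None
        img, n_blobs, wedge = _render_view(rng, config, silhouette, sigma_c, proj == "MLO", this_lesion)
        n_blobs_total += n_blobs
        lesion_here = this_lesion
        if side == "R":  # anatomical mirroring: chest wall on the right in stored files
            img = np.fliplr(img)
            wedge = np.fliplr(wedge)
            sil = np.fliplr(silhouette)
            if lesion_here is not None:
                lesion_here = (lesion_here[0], size - 1 - lesion_here[1])
        else:
            sil = silhouette
        views[view] = img
        silhouettes[view] = sil
        wedges[view] = wedge
        if lesion_here is not None:
            lesion_coords[view] = lesion_here

    return CaseRecord(
        case_id=f"case{case_index:03d}", cancer=cancer, views=views,
        lesion_side=lesion_side, lesion_coords=lesion_coords,
        mean_blob_sigma=sigma_c, n_blobs=n_blobs_total // len(VIEWS),
        silhouettes=silhouettes, wedges=wedges,
    )


def generate_cohort(config: SyntheticConfig) -> tuple[list[CaseRecord], list[GroundTruthDifficulty]]:
    """All cases plus ground-truth difficulty (d_c standardized over cohort)."""
    cases = [generate_case(config, i) for i in range(config.n_cases)]
    sigmas = np.array([c.mean_blob_sigma for c in cases])
    sd = sigmas.std(ddof=0)
    d = (sigmas - sigmas.mean()) / sd if sd > 0 else np.zeros_like(sigmas)
    truths = []
    for case, d_c in zip(cases, d):
        p = float(expit(config.error_link_intercept + config.error_link_slope * d_c))
        bases = {"FP": p} if not case.cancer else {"FN": p, "location": p}
        truths.append(GroundTruthDifficulty(case.case_id, float(d_c), bases))
    return cases, truths


def _annulus_point(rng, center, radius, silhouette):
    """Uniform draw on the annulus (radius, 2*radius], rejected onto the breast."""
    size = silhouette.shape[0]
    for _ in range(200):
        rho = radius * np.sqrt(rng.uniform(1.0, 4.0))  # area-uniform on (r, 2r]
        phi = rng.uniform(0, 2 * np.pi)
        r = int(round(center[0] + rho * np.sin(phi)))
        c = int(round(center[1] + rho * np.cos(phi)))
        # pixel rounding must not collapse the draw back onto the correct radius
        if (0 <= r < size and 0 <= c < size and silhouette[r, c]
                and np.hypot(r - center[0], c - center[1]) > radius):
            return r, c
    # fall back toward the breast centroid, still outside the radius
    rr, cc = np.nonzero(silhouette)
    cen = rr.mean(), cc.mean()
    vec = np.array([cen[0] - center[0], cen[1] - center[1]])
    vec = vec / max(1e-9, np.hypot(*vec)) * 1.5 * radius
    return int(center[0] + vec[0]), int(center[1] + vec[1])


def simulate_reader_panel(
    cases: list[CaseRecord],
    truths: list[GroundTruthDifficulty],
    config: SyntheticConfig,
) -> list[ReaderResponse]:
    """Bernoulli reader errors driven by latent difficulty through the link.

    Cancer-free cases: an error is a false positive (rating 3-5 with a
    random in-breast annotation), otherwise rating 1-2.  Cancer cases: an
    error is, with probability ``localization_error_fraction``, a
    localization error (rating 3-5, annotation displaced onto the annulus
    (radius, 2*radius] around the lesion) and otherwise a false negative
    (rating 1-2, no annotation); a non-error rates 3-5 and annotates within
    half the correct-localization radius.
    """
    if len(cases) != len(truths):
        raise InputError("one GroundTruthDifficulty per case required")
    by_id = {t.case_id: t for t in truths}
    if any(c.case_id not in by_id for c in cases):
        raise InputError("case/truth id mismatch")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_READERS)))
    biases = rng.normal(0.0, config.reader_bias_sd, size=config.n_readers)
    radius = config.loc_radius
    responses = []
    for ridx in range(config.n_readers):
        reader_id = f"reader{ridx:02d}"
        for case in cases:
            d_c = by_id[case.case_id].latent_difficulty
            p_err = expit(config.error_link_intercept + config.error_link_slope * d_c + biases[ridx])
            err = rng.random() < p_err
            if not case.cancer:
                if err:
                    view = VIEWS[rng.integers(0, len(VIEWS))]
                    rr, cc = np.nonzero(case.silhouettes[view])
                    k = int(rng.integers(0, rr.size))
                    responses.append(ReaderResponse(reader_id, case.case_id,
                                                    int(rng.integers(3, 6)), view,
                                                    float(cc[k]), float(rr[k])))
                else:
                    responses.append(ReaderResponse(reader_id, case.case_id, int(rng.integers(1, 3))))
            else:
                lesion_views = sorted(case.lesion_coords)
                view = lesion_views[int(rng.integers(0, len(lesion_views)))]
                lr, lc = case.lesion_coords[view]
                if err and rng.random() < config.localization_error_fraction:
                    r, c = _annulus_point(rng, (lr, lc), radius, case.silhouettes[view])
                    responses.append(ReaderResponse(reader_id, case.case_id,
                                                    int(rng.integers(3, 6)), view, float(c), float(r)))
                elif err:
                    responses.append(ReaderResponse(reader_id, case.case_id, int(rng.integers(1, 3))))
                else:
                    rho = 0.5 * radius * np.sqrt(rng.random())
                    phi = rng.uniform(0, 2 * np.pi)
                    responses.append(ReaderResponse(
                        reader_id, case.case_id, int(rng.integers(3, 6)), view,
                        float(lc + rho * np.cos(phi)), float(lr + rho * np.sin(phi))))
    return responses


# ---------------------------------------------------------------- I/O

def responses_frame(responses: list[ReaderResponse]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in responses])


def truth_frame(cases: list[CaseRecord]) -> pd.DataFrame:
    rows = []
    for c in cases:
        if c.cancer:
            for view, (r, col) in sorted(c.lesion_coords.items()):
                rows.append({"case_id": c.case_id, "cancer": True, "lesion_view": view,
                             "lesion_x": col, "lesion_y": r, "lesion_side": c.lesion_side})
        else:
            rows.append({"case_id": c.case_id, "cancer": False, "lesion_view": None,
                         "lesion_x": None, "lesion_y": None, "lesion_side": None})
    return pd.DataFrame(rows)


def write_cohort(outdir, cases, truths, responses, config: SyntheticConfig) -> dict:
    """Write 16-bit PNG views, truth/response CSVs and a manifest JSON."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    hi = max(c.views[v].max() for c in cases for v in VIEWS)
    for c in cases:
        for view in VIEWS:
            img16 = np.round(c.views[view] / hi * 65535).astype(np.uint16)
            iio.imwrite(outdir / "images" / f"{c.case_id}_{view}.png", img16)
    truth_frame(cases).to_csv(outdir / "truth.csv", index=False)
    responses_frame(responses).to_csv(outdir / "responses.csv", index=False)
    pd.DataFrame(
        {"case_id": [t.case_id for t in truths],
         "latent_difficulty": [t.latent_difficulty for t in truths]}
    ).to_csv(outdir / "latent_difficulty.csv", index=False)
    manifest = {"config": dataclasses.asdict(config), "intensity_scale": float(hi),
                "n_cases": len(cases), "n_responses": len(responses)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
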
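"""Synthetic paired report + slide benchmark with known ground truth.

Every case couples a free-text colon report with a slide raster whose tissue
is painted with class-specific gland-like textures on a white background.
Texture parameters follow the morphology gradient of the five classes: gland
deformation and epithelial solidity increase strictly from normal mucosa
through hyperplastic polyp and low-/high-grade dysplasia to cancer, so the
classes are distinguishable by construction while remaining non-trivial
(colour jitter, lattice jitter, azimuthal deformation).

The generator records per-pixel and per-patch ground truth, supports
corpus-level class imbalance, report noise (negated phrases for absent
classes, the documented resection-margin distractor clause) and an
injectable slide-label noise rate that emulates the 15-25% error rate of
automatic report labeling, with a manifest of exactly which cases were
corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labeler import ReportRecord
from .preprocess import SlideRaster
from .schema import AnnotationClass, CLASS_NAMES, as_label, label_classes, make_label


class SynthesisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Textures


@dataclass(frozen=True)
class ClassTextureSpec:
    """Procedural gland texture parameters for one class."""

    ring_spacing: float  # gland lattice spacing, px at 10x
    deformation: float  # azimuthal ring deformation amplitude (fraction)
    solidity: float  # epithelial ring thickness as fraction of gland radius
    stroma_rgb: tuple[int, int, int]
    epithelium_rgb: tuple[int, int, int]
    color_jitter: float = 8.0  # per-pixel uniform RGB jitter, 8-bit scale


#: Deformation and solidity strictly ordered normal < hyperplastic < LGD < HGD < cancer.
TEXTURES: dict[AnnotationClass, ClassTextureSpec] = {
    AnnotationClass.normal: ClassTextureSpec(28.0, 0.05, 0.25, (233, 172, 198), (150, 90, 160)),
    AnnotationClass.hyperplastic_polyp: ClassTextureSpec(34.0, 0.12, 0.35, (234, 176, 205), (140, 85, 155)),
    AnnotationClass.low_grade_dysplasia: ClassTextureSpec(24.0, 0.25, 0.50, (228, 163, 193), (125, 70, 150)),
    AnnotationClass.high_grade_dysplasia: ClassTextureSpec(20.0, 0.40, 0.65, (218, 146, 183), (105, 55, 140)),
    AnnotationClass.cancer: ClassTextureSpec(16.0, 0.60, 0.85, (205, 128, 172), (85, 40, 125)),
}

_ORDERED = [
    AnnotationClass.normal,
    AnnotationClass.hyperplastic_polyp,
    AnnotationClass.low_grade_dysplasia,
    AnnotationClass.high_grade_dysplasia,
    AnnotationClass.cancer,
]
assert all(
    TEXTURES[a].deformation < TEXTURES[b].deformation
    and TEXTURES[a].solidity < TEXTURES[b].solidity
    for a, b in zip(_ORDERED, _ORDERED[1:])
)

BACKGROUND = 255
_LUMEN_RGB = np.array((250, 243, 248), dtype=np.float32)


def _render_texture(
    yy: np.ndarray, xx: np.ndarray, spec: ClassTextureSpec, rng: np.random.Generator
) -> np.ndarray:
    """Paint a gland lattice texture over the given coordinate grid (uint8 RGB).

    ``yy``/``xx`` are broadcastable global pixel coordinates, so the pattern
    is translation-consistent when rendered over a sub-window.
    """
    s = np.float32(spec.ring_spacing)
    # gland-local coordinates on a jittered lattice
    cell_x = np.floor(xx / s)
    cell_y = np.floor(yy / s)
    jitter_x = 0.22 * s * np.sin(12.9898 * cell_x + 78.233 * cell_y)
    jitter_y = 0.22 * s * np.sin(39.3467 * cell_x + 11.135 * cell_y)
    u = xx - (cell_x + np.float32(0.5)) * s - jitter_x
    v = yy - (cell_y + np.float32(0.5)) * s - jitter_y
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)
    phase = 6.2831 * np.sin(5.31 * cell_x + 7.17 * cell_y)
    r0 = 0.34 * s * (1.0 + np.float32(spec.deformation) * np.sin(3.0 * theta + phase))
    inner = r0 * np.float32(1.0 - spec.solidity)
    out = np.empty((*r.shape, 3), dtype=np.float32)
    out[:] = spec.stroma_rgb
    out[r < inner] = _LUMEN_RGB
    out[(r >= inner) & (r <= r0)] = spec.epithelium_rgb
    out += rng.uniform(-spec.color_jitter, spec.color_jitter, size=out.shape).astype(np.float32)
    return np.clip(out, 0, 255).astype(np.uint8)


def synth_slide(
    labels, size: int = 1120, seed: int | np.random.Generator = 0, patch_size: int = 224
) -> tuple[SlideRaster, np.ndarray, np.ndarray]:
    """Render a slide for a finalized label vector.

    One elliptical tissue region per set class, painted with that class's
    texture on a white background, regions non-overlapping (vertical bands).
    Returns (slide at base 10x, region_mask with class index or -1, patch_gt
    grid with class index or -1).  Per-cell ground truth is the class
    covering at least half of the cell's tissue.  Deterministic given seed.
    """
    labels = as_label(labels)
    classes = sorted(label_classes(labels))
    if not classes:
        raise SynthesisError("slide synthesis needs a finalized label (>=1 class)")
    if size < patch_size:
        raise SynthesisError(f"size {size} smaller than one patch ({patch_size})")
    band = size // len(classes)
    if band < patch_size:
        raise SynthesisError(
            f"too many classes ({len(classes)}) for size {size}: band {band} < patch {patch_size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pixels = np.full((size, size, 3), BACKGROUND, dtype=np.uint8)
    region_mask = np.full((size, size), -1, dtype=np.int8)
    yy = np.arange(size, dtype=np.float32)[:, None]
    for i, cls in enumerate(classes):
        x0, x1 = i * band, (i + 1) * band
        xx = np.arange(x0, x1, dtype=np.float32)[None, :]
        cx = np.float32((i + 0.5) * band)
        cy = np.float32(size / 2.0)
        rx = np.float32(0.46 * band)
        ry = np.float32(0.46 * size)
        wobble = 1.0 + 0.06 * np.sin(
            6.0 * np.arctan2(yy - cy, xx - cx) + np.float32(rng.uniform(0, 6.28))
        )
        inside = ((xx - cx) / (rx * wobble)) ** 2 + ((yy - cy) / (ry * wobble)) ** 2 <= 1.0
        texture = _render_texture(yy, xx, TEXTURES[cls], rng)
        pixels[:, x0:x1][inside] = texture[inside]
        region_mask[:, x0:x1][inside] = int(cls)

    grid = size // patch_size
    patch_gt = np.full((grid, grid), -1, dtype=np.int8)
    for gy in range(grid):
        for gx in range(grid):
            cell = region_mask[
                gy * patch_size : (gy + 1) * patch_size,
                gx * patch_size : (gx + 1) * patch_size,
            ]
            tissue = cell[cell >= 0]
            if tissue.size == 0:
                continue
            counts = np.bincount(tissue, minlength=5)
            top = int(counts.argmax())
            if counts[top] >= 0.5 * tissue.size:
                patch_gt[gy, gx] = top
    slide = SlideRaster(
        levels=[pixels], base_magnification=10.0, downsamples=[1.0], slide_id=""
    )
    return slide, region_mask, patch_gt


# ---------------------------------------------------------------------------
# Reports


_PHRASES: dict[AnnotationClass, list[str]] = {
    AnnotationClass.cancer: [
        "infiltrating adenocarcinoma",
        "moderately differentiated adenocarcinoma",
        "invasive adenocarcinoma of the colon",
    ],
    AnnotationClass.high_grade_dysplasia: [
        "high-grade dysplasia",
        "severe dysplasia",
        "fragments with high grade dysplasia",
    ],
    AnnotationClass.low_grade_dysplasia: [
        "tubular adenoma with low-grade dysplasia",
        "low-grade dysplasia",
        "mild dysplasia in tubular adenoma",
    ],
    AnnotationClass.hyperplastic_polyp: [
        "hyperplastic polyp",
        "serrated polyp with hyperplastic features",
    ],
    AnnotationClass.normal: [
        "normal colonic mucosa",
        "unremarkable mucosa",
        "fragments of normal mucosa",
    ],
}

_NEGATED_TERM: dict[AnnotationClass, str] = {
    AnnotationClass.cancer: "adenocarcinoma",
    AnnotationClass.high_grade_dysplasia: "high-grade dysplasia",
    AnnotationClass.low_grade_dysplasia: "low-grade dysplasia",
    AnnotationClass.hyperplastic_polyp: "hyperplastic polyp",
}

DISTRACTOR_CLAUSE = "margin of resection on hyperplasia-adenomatous mucosa"

_NO_FINDINGS = "fragments of colonic tissue without significant alterations"


def synth_report(
    labels,
    noise: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
    report_id: str = "synth",
    case_ids: tuple[str, ...] = (),
) -> ReportRecord:
    """Phrase a finalized label vector as a colon pathology report.

    Each set class contributes one affirmative template phrase; pure-normal
    cases omit findings with probability 0.5 (exercising the fallback path).
    With probability ``noise[0]`` a negated phrase for an unset class is
    appended; with probability ``noise[1]`` the resection-margin distractor
    clause is appended when hyperplastic polyp is unset.  Seeded.
    """
    labels = as_label(labels)
    classes = sorted(label_classes(labels))
    if not classes:
        raise SynthesisError("report synthesis needs a finalized label")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    negation_rate, distractor_rate = noise

    sentences = ["colon, biopsy"]
    if classes == [AnnotationClass.normal] and rng.random() < 0.5:
        sentences.append(_NO_FINDINGS)
    else:
        for cls in classes:
            options = _PHRASES[cls]
            sentences.append(options[int(rng.integers(len(options)))])
    if negation_rate > 0 and rng.random() < negation_rate:
        unset = [c for c in _NEGATED_TERM if labels[int(c)] == 0]
        if unset:
            target = unset[int(rng.integers(len(unset)))]
            sentences.append(f"no {_NEGATED_TERM[target]}")
    if (
        distractor_rate > 0
        and labels[int(AnnotationClass.hyperplastic_polyp)] == 0
        and rng.random() < distractor_rate
    ):
        sentences.append(DISTRACTOR_CLAUSE)
    text = ". ".join(sentences) + "."
    return ReportRecord(report_id=report_id, text=text, case_ids=case_ids, source_language="en")


# ---------------------------------------------------------------------------
# Corpus


#: Default label-set prevalence: imbalance shaped like a screening workflow
#: (normal most frequent, low-grade dysplasia next, double-dysplasia and
#: cancer+HGD combinations present but rare).
DEFAULT_PREVALENCE: dict[frozenset, float] = {
    frozenset({"normal"}): 0.30,
    frozenset({"low_grade_dysplasia"}): 0.22,
    frozenset({"hyperplastic_polyp"}): 0.14,
    frozenset({"cancer"}): 0.12,
    frozenset({"high_grade_dysplasia"}): 0.08,
    frozenset({"cancer", "high_grade_dysplasia"}): 0.06,
    frozenset({"high_grade_dysplasia", "low_grade_dysplasia"}): 0.05,
    frozenset({"low_grade_dysplasia", "hyperplastic_polyp"}): 0.03,
}


@dataclass
class CorpusConfig:
    n_cases: int = 50
    class_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    slide_size: int = 1120
    mislabel_rate: float = 0.0
    negation_rate: float = 0.0
    distractor_rate: float = 0.0
    bags_per_patient: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("mislabel_rate", "negation_rate", "distractor_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SynthesisError(f"{name} must be in [0, 1]")
        total = sum(self.class_prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise SynthesisError(f"class prevalence sums to {total}, expected 1")


@dataclass
class SyntheticCase:
    case_id: str
    patient_id: str
    slide: SlideRaster | None
    region_mask: np.ndarray | None
    patch_gt: np.ndarray | None
    report: ReportRecord
    gt_label: np.ndarray
    noisy_label: np.ndarray | None = None
    corrupted: bool = False


def sample_label_sets(config: CorpusConfig, rng: np.random.Generator) -> list[frozenset]:
    """Draw n label sets from the configured prevalence distribution."""
    keys = list(config.class_prevalence)
    probs = np.array([config.class_prevalence[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=config.n_cases, p=probs)
    return [frozenset(keys[i]) for i in idx]


def _flip_one_class(label: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Flip one uniformly chosen class indicator, keeping >=1 class set."""
    candidates = list(range(5))
    if label.sum() == 1:
        candidates.remove(int(np.flatnonzero(label)[0]))
    flip = candidates[int(rng.integers(len(candidates)))]
    noisy = label.copy()
    noisy[flip] ^= 1
    return noisy, flip


def synth_corpus(
    config: CorpusConfig, render_slides: bool = True
) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Generate a corpus of paired cases plus a manifest of every corruption.

    Exactly floor(mislabel_rate * n) cases receive a noisy label with one
    class indicator flipped.  Patients are assigned round-robin with
    ``bags_per_patient`` cases each.  Slide rendering can be skipped for
    text-only studies.
    """
    master = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    label_sets = sample_label_sets(config, rng)
    n = config.n_cases
    n_corrupt = int(np.floor(config.mislabel_rate * n))
    corrupt_ids = set(rng.choice(n, size=n_corrupt, replace=False).tolist())

    case_seeds = master.spawn(n)
    cases: list[SyntheticCase] = []
    manifest_rows = []
    for i in range(n):
        case_rng = np.random.default_rng(case_seeds[i])
        case_id = f"case{i:04d}"
        patient_id = f"pt{i // config.bags_per_patient:04d}"
        gt_label = make_label(label_sets[i])
        slide = region_mask = patch_gt = None
        if render_slides:
            slide, region_mask, patch_gt = synth_slide(
                gt_label, size=config.slide_size, seed=case_rng
            )
            slide.slide_id = case_id
        report = synth_report(
            gt_label,
            noise=(config.negation_rate, config.distractor_rate),
            seed=case_rng,
            report_id=f"{case_id}-rep",
            case_ids=(case_id,),
        )
        noisy_label, flipped = None, -1
        corrupted = i in corrupt_ids
        if corrupted:
            noisy_label, flipped = _flip_one_class(gt_label, case_rng)
        cases.append(
            SyntheticCase(
                case_id=case_id,
                patient_id=patient_id,
                slide=slide,
                region_mask=region_mask,
                patch_gt=patch_gt,
                report=report,
                gt_label=gt_label,
                noisy_label=noisy_label,
                corrupted=corrupted,
            )
        )
        manifest_rows.append(
            {
                "case_id": case_id,
                "patient_id": patient_id,
                "label_set": "|".join(sorted(c.name for c in label_classes(gt_label))),
                "corrupted": corrupted,
                "flipped_class": CLASS_NAMES[flipped] if flipped >= 0 else "",
            }
        )
    return cases, pd.DataFrame(manifest_rows)


def corpus_label_frames(cases: list[SyntheticCase]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth and noisy (training) label tables for a corpus."""
    from .schema import labels_to_frame

    ids = [c.case_id for c in cases]
    gt = np.vstack([c.gt_label for c in cases])
    noisy = np.vstack(
        [c.noisy_label if c.noisy_label is not None else c.gt_label for c in cases]
    )
    return labels_to_frame(ids, gt), labels_to_frame(ids, noisy)
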
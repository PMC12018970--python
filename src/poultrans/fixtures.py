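"""Synthetic image-caption corpora with controlled statistical structure.

Real poultry-condition photographs are large and cannot ship with the
package, so every stage of the pipeline is exercised on procedurally drawn
corpora instead.  Each image renders a sampled (entity, condition,
body-part, colour) attribute tuple as unambiguous visual primitives:

* the entity decides the body silhouette (ellipse / rectangle / triangle),
* the colour decides the silhouette's fill,
* the condition decides the colour of a small square marker,
* the body part decides where on the silhouette the marker sits.

The paired caption is a template filled with exactly those attribute words,
so caption content is fully predictable from pixel content — the structure
a captioner must learn, minus photographic nuisance.  A rule-based pixel
classifier (:func:`classify_image`) recovers the generating attributes and
serves as an independent check that the rendering is information-preserving.

:func:`generate_alignment_batch` builds paired image/text feature vectors
with a controlled similarity margin for testing the contrastive loss in
isolation.  Base vectors are orthonormalised so that with zero noise the
true-pair similarity matrix is exactly the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .dataset_io import CaptionRecord, tokenize, write_captions

__all__ = [
    "FixtureSpec",
    "generate_corpus",
    "classify_image",
    "generate_alignment_batch",
    "golden_spec",
    "GOLDEN_SEED",
]

GOLDEN_SEED = 7

_BACKGROUND = (255, 255, 255)
_SHAPES = ("ellipse", "rectangle", "triangle")
_FILL_PALETTE = {
    "red": (220, 30, 30),
    "blue": (30, 60, 220),
    "brown": (150, 90, 40),
    "gray": (128, 128, 128),
    "green": (30, 160, 60),
    "yellow": (230, 200, 30),
}
_MARKER_PALETTE = ((0, 0, 0), (255, 0, 255), (0, 200, 255), (255, 128, 0))
# body-part slot -> marker offset from the silhouette centre, in half-size units
_PART_OFFSETS = ((0.0, -1.25), (-1.25, 0.0), (0.0, 1.25), (1.25, 0.0))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic corpus; the seed fixes it bit-exactly."""

    n_images: int = 20
    entities: tuple[str, ...] = ("chicken", "duck")
    conditions: tuple[str, ...] = ("healthy", "sick")
    body_parts: tuple[str, ...] = ("head", "wing")
    colors: tuple[str, ...] = ("red", "blue")
    image_size: int = 224
    caption_templates: tuple[str, ...] = ("a {color} {entity} with a {condition} {body_part}",)
    seed: int = GOLDEN_SEED

    def __post_init__(self):
        for name, val in (
            ("entities", self.entities),
            ("conditions", self.conditions),
            ("body_parts", self.body_parts),
            ("colors", self.colors),
            ("caption_templates", self.caption_templates),
        ):
            if not val:
                raise ValueError(f"{name} must be non-empty")
        if len(self.entities) > len(_SHAPES):
            raise ValueError(f"at most {len(_SHAPES)} entities supported")
        if len(self.conditions) > len(_MARKER_PALETTE):
            raise ValueError(f"at most {len(_MARKER_PALETTE)} conditions supported")
        if len(self.body_parts) > len(_PART_OFFSETS):
            raise ValueError(f"at most {len(_PART_OFFSETS)} body parts supported")
        unknown = set(self.colors) - set(_FILL_PALETTE)
        if unknown:
            raise ValueError(f"unknown colors {sorted(unknown)}; palette: {sorted(_FILL_PALETTE)}")

    def vocabulary_tokens(self) -> set[str]:
        """Closed-form token set of every caption this recipe can emit."""
        toks: set[str] = set()
        for tpl in self.caption_templates:
            toks.update(
                tokenize(
                    tpl.format(color="", entity="", condition="", body_part="")
                )
            )
        toks.update(self.entities)
        toks.update(self.conditions)
        toks.update(self.body_parts)
        toks.update(self.colors)
        return toks

    def max_caption_tokens(self) -> int:
        """Upper bound on tokenized caption length (attributes are 1 token each)."""
        return max(
            len(tokenize(tpl.format(color="c", entity="e", condition="s", body_part="p")))
            for tpl in self.caption_templates
        )


def _draw_image(size: int, shape: str, fill: tuple, marker: tuple, offset: tuple) -> Image.Image:
    img = Image.new("RGB", (size, size), _BACKGROUND)
    draw = ImageDraw.Draw(img)
    cx = cy = size // 2
    half = int(size * 0.27)
    box = (cx - half, cy - half, cx + half, cy + half)
    if shape == "ellipse":
        draw.ellipse(box, fill=fill)
    elif shape == "rectangle":
        draw.rectangle(box, fill=fill)
    else:
        draw.polygon([(cx, cy - half), (cx - half, cy + half), (cx + half, cy + half)], fill=fill)
    mx = cx + int(offset[0] * half)
    my = cy + int(offset[1] * half)
    m = max(6, size // 28)
    draw.rectangle((mx - m, my - m, mx + m, my + m), fill=marker)
    return img


def generate_corpus(spec: FixtureSpec, out_dir: str | Path) -> tuple[list[CaptionRecord], Path]:
    """Render ``spec.n_images`` images + captions; returns (records, json path)."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "images").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_images):
        ent_i = int(rng.integers(len(spec.entities)))
        con_i = int(rng.integers(len(spec.conditions)))
        part_i = int(rng.integers(len(spec.body_parts)))
        col_i = int(rng.integers(len(spec.colors)))
        tpl_i = int(rng.integers(len(spec.caption_templates)))
        color = spec.colors[col_i]
        img = _draw_image(
            spec.image_size,
            _SHAPES[ent_i],
            _FILL_PALETTE[color],
            _MARKER_PALETTE[con_i],
            _PART_OFFSETS[part_i],
        )
        fname = f"images/fixture_{i:04d}.png"
        img.save(out_dir / fname)
        caption = spec.caption_templates[tpl_i].format(
            color=color,
            entity=spec.entities[ent_i],
            condition=spec.conditions[con_i],
            body_part=spec.body_parts[part_i],
        )
        records.append(CaptionRecord(image_id=f"{i:04d}", image_path=fname, captions=(caption,)))
    json_path = out_dir / "captions.json"
    write_captions(records, json_path)
    return records, json_path


def classify_image(path_or_array, spec: FixtureSpec) -> dict[str, str]:
    """Recover the generating attributes of a fixture image from pixels alone.

    Independent of the generator's sampling: works purely from fill-colour
    counts, silhouette fill-fraction (shape identity) and marker position.
    """
    if isinstance(path_or_array, (str, Path)):
        arr = np.asarray(Image.open(path_or_array).convert("RGB"))
    else:
        arr = np.asarray(path_or_array)
    # colour: the fill palette entry with the most exact-match pixels
    counts = {
        name: int(np.all(arr == np.array(rgb), axis=-1).sum())
        for name, rgb in _FILL_PALETTE.items()
        if name in spec.colors
    }
    color = max(counts, key=counts.get)
    if counts[color] == 0:
        raise ValueError("no fill-colour pixels found; not a fixture image")
    mask = np.all(arr == np.array(_FILL_PALETTE[color]), axis=-1)
    ys, xs = np.nonzero(mask)
    bbox_area = (ys.max() - ys.min() + 1) * (xs.max() - xs.min() + 1)
    frac = mask.sum() / bbox_area
    # fill fraction of the bounding box: rectangle ~1, ellipse ~pi/4, triangle ~1/2
    if frac > 0.9:
        shape = "rectangle"
    elif frac > 0.65:
        shape = "ellipse"
    else:
        shape = "triangle"
    entity = spec.entities[_SHAPES.index(shape)]
    # condition: which marker colour is present
    condition = None
    for ci, rgb in enumerate(_MARKER_PALETTE[: len(spec.conditions)]):
        mmask = np.all(arr == np.array(rgb), axis=-1)
        if mmask.sum() >= 9:
            condition = spec.conditions[ci]
            mys, mxs = np.nonzero(mmask)
            break
    if condition is None:
        raise ValueError("no condition marker found; not a fixture image")
    # body part: marker centroid direction from the silhouette centre
    cy, cx = ys.mean(), xs.mean()
    dy, dx = mys.mean() - cy, mxs.mean() - cx
    direction = np.array([[0.0, -1.0], [-1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
    scores = direction @ np.array([dx, dy])
    part_i = int(np.argmax(scores[: len(spec.body_parts)]))
    return {
        "entity": entity,
        "condition": condition,
        "body_part": spec.body_parts[part_i],
        "color": color,
    }


def golden_spec() -> FixtureSpec:
    """The fixed 20-image, seed-7 corpus used for deterministic tests."""
    return FixtureSpec(n_images=20, seed=GOLDEN_SEED)


# -- alignment features --------------------------------------------------------


def _orthonormal_rows(rng: np.random.Generator, n_rows: int, dim: int) -> np.ndarray:
    if n_rows <= dim:
        q, _ = np.linalg.qr(rng.normal(size=(dim, n_rows)))
        return q.T
    rows = rng.normal(size=(n_rows, dim))
    return rows / np.linalg.norm(rows, axis=1, keepdims=True)


def generate_alignment_batch(
    n: int,
    dim_image: int = 2048,
    dim_text: int = 1198,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired image/text features whose true pairing has a similarity margin.

    Returns ``(image_features (n, dim_image), text_features (n, dim_text),
    pairing (n,))`` where ``pairing[i] = i``: row i of each side belongs to
    the same underlying item.  Text features are positively scaled latent
    copies plus Gaussian noise; when ``dim_image == dim_text`` and
    ``noise_sd == 0`` the text rows are exact scaled copies of the image
    rows, so true-pair cosine similarity is 1 and (because the latent rows
    are orthonormal for n <= dim) mismatched-pair similarity is 0.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    d = min(dim_image, dim_text)
    latent = _orthonormal_rows(rng, n, d)
    basis_img = _orthonormal_rows(rng, d, dim_image)
    basis_txt = basis_img[:, :dim_text] if dim_image == dim_text else _orthonormal_rows(rng, d, dim_text)
    image = latent @ basis_img
    scales = rng.uniform(0.5, 2.0, size=(n, 1))
    text = scales * (latent @ basis_txt)
    if noise_sd > 0:
        text = text + noise_sd * rng.normal(size=text.shape)
    return image, text, np.arange(n)
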
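"""Reading, tokenising and encoding COCO-Captions-style corpora.

The annotation dialect is the familiar COCO-Captions JSON: a top-level
``images`` array (``id``, ``file_name``) and an ``annotations`` array
(``image_id``, ``caption``).  Vocabulary construction indexes every token
whose training-corpus frequency reaches ``min_freq`` (default 2); rarer
tokens encode to ``<unk>``.  Special symbols occupy fixed ids so encoded
corpora are reproducible across runs: ``<pad>``=0, ``<start>``=1,
``<end>``=2, ``<unk>``=3.

Images are preprocessed to the model's 3x224x224 input contract: resize the
shorter side to 256 then take a 224 crop (random in training, centred in
evaluation), scale to [0,1] and apply channel normalisation (identity by
default; mean/std statistics can be supplied when a pretrained backbone
checkpoint is in use).
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CaptionRecord",
    "Vocabulary",
    "EncodedCaption",
    "CaptionFormatError",
    "PAD", "START", "END", "UNK",
    "read_captions",
    "write_captions",
    "tokenize",
    "build_vocab",
    "encode_caption",
    "decode_caption",
    "split_dataset",
    "preprocess_image",
    "load_image",
]

PAD, START, END, UNK = 0, 1, 2, 3
SPECIALS = ("<pad>", "<start>", "<end>", "<unk>")

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


class CaptionFormatError(ValueError):
    """Raised when an annotation file violates the COCO-Captions dialect."""


@dataclass(frozen=True)
class CaptionRecord:
    """One image together with all of its reference captions."""

    image_id: str
    image_path: str
    captions: tuple[str, ...]

    def __post_init__(self):
        if not self.captions:
            raise CaptionFormatError(f"image {self.image_id!r} has no captions")


@dataclass
class EncodedCaption:
    """Fixed-length id sequence: <start> tokens... <end> <pad>..."""

    ids: np.ndarray
    length: int


@dataclass
class Vocabulary:
    """Token<->id bijection with fixed special symbols.

    Non-special ids are assigned by descending corpus frequency, ties broken
    lexicographically, so construction is deterministic.
    """

    token_to_id: dict[str, int]
    min_freq: int
    id_to_token: dict[int, str] = field(init=False)

    def __post_init__(self):
        for i, s in enumerate(SPECIALS):
            if self.token_to_id.get(s) != i:
                raise ValueError(f"special token {s} must have id {i}")
        if len(set(self.token_to_id.values())) != len(self.token_to_id):
            raise ValueError("token_to_id is not injective")
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}

    def __len__(self) -> int:
        return len(self.token_to_id)

    def encode_token(self, token: str) -> int:
        return self.token_to_id.get(token, UNK)

    def decode_id(self, idx: int) -> str:
        return self.id_to_token.get(int(idx), SPECIALS[UNK])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"min_freq": self.min_freq, "token_to_id": self.token_to_id}, indent=0, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        blob = json.loads(Path(path).read_text())
        return cls(token_to_id=blob["token_to_id"], min_freq=int(blob["min_freq"]))


# -- annotation I/O -----------------------------------------------------------


def read_captions(path: str | Path) -> list[CaptionRecord]:
    """Read a COCO-Captions JSON file into records sorted by image_id."""
    path = Path(path)
    blob = json.loads(path.read_text())
    if "images" not in blob or "annotations" not in blob:
        raise CaptionFormatError(f"{path}: missing 'images' or 'annotations' array")
    paths: dict[str, str] = {}
    for img in blob["images"]:
        iid = str(img["id"])
        if iid in paths:
            raise CaptionFormatError(f"{path}: duplicate image id {iid!r}")
        paths[iid] = img["file_name"]
    caps: dict[str, list[str]] = {iid: [] for iid in paths}
    for ann in blob["annotations"]:
        iid = str(ann["image_id"])
        if iid not in caps:
            raise CaptionFormatError(f"{path}: annotation references unknown image id {iid!r}")
        caps[iid].append(str(ann["caption"]))
    records = []
    for iid in sorted(paths):
        if not caps[iid]:
            raise CaptionFormatError(f"{path}: image id {iid!r} has no annotations")
        records.append(CaptionRecord(image_id=iid, image_path=paths[iid], captions=tuple(caps[iid])))
    return records


def write_captions(records: list[CaptionRecord], path: str | Path) -> None:
    """Write records back to the COCO-Captions dialect (inverse of read)."""
    images = [{"id": r.image_id, "file_name": r.image_path} for r in sorted(records, key=lambda r: r.image_id)]
    annotations = []
    for r in sorted(records, key=lambda r: r.image_id):
        for c in r.captions:
            annotations.append({"image_id": r.image_id, "caption": c})
    Path(path).write_text(json.dumps({"images": images, "annotations": annotations}, indent=0, sort_keys=True))


# -- text ----------------------------------------------------------------------


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return text.lower().translate(_PUNCT_TABLE).split()


def build_vocab(records: list[CaptionRecord], min_freq: int = 2) -> Vocabulary:
    """Index tokens whose corpus frequency is at least ``min_freq``."""
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    if not records:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    for r in records:
        for cap in r.captions:
            for tok in tokenize(cap):
                counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_freq and t not in SPECIALS),
        key=lambda t: (-counts[t], t),
    )
    token_to_id = {s: i for i, s in enumerate(SPECIALS)}
    for off, tok in enumerate(kept):
        token_to_id[tok] = len(SPECIALS) + off
    return Vocabulary(token_to_id=token_to_id, min_freq=min_freq)


def encode_caption(tokens: list[str], vocab: Vocabulary, max_len: int) -> EncodedCaption:
    """Frame with <start>/<end>, pad to ``max_len``; truncation keeps <end>."""
    if max_len < 3:
        raise ValueError("max_len must be >= 3")
    body = [vocab.encode_token(t) for t in tokens][: max_len - 2]
    ids = np.full(max_len, PAD, dtype=np.int64)
    ids[0] = START
    ids[1 : 1 + len(body)] = body
    ids[1 + len(body)] = END
    return EncodedCaption(ids=ids, length=len(body) + 2)


def decode_caption(ids: np.ndarray, vocab: Vocabulary) -> list[str]:
    """Strip framing/padding and map ids back to tokens (<unk> kept literal)."""
    out = []
    for idx in np.asarray(ids).tolist():
        if idx == START or idx == PAD:
            continue
        if idx == END:
            break
        out.append(vocab.decode_id(idx))
    return out


# -- splitting -----------------------------------------------------------------


def split_dataset(
    records: list[CaptionRecord], ratio: float = 0.8, seed: int = 0
) -> tuple[list[CaptionRecord], list[CaptionRecord]]:
    """Disjoint, exhaustive train/validation split; deterministic under seed."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    order = np.random.default_rng(seed).permutation(len(records))
    n_train = int(round(ratio * len(records)))
    n_train = min(max(n_train, 1), len(records) - 1)
    train_idx = set(order[:n_train].tolist())
    train = [r for i, r in enumerate(records) if i in train_idx]
    val = [r for i, r in enumerate(records) if i not in train_idx]
    return train, val


# -- images --------------------------------------------------------------------


def load_image(path: str | Path) -> Image.Image:
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return img.convert("RGB")


def preprocess_image(
    image: Image.Image,
    mode: str = "eval",
    seed: int = 0,
    mean: tuple[float, float, float] | None = None,
    std: tuple[float, float, float] | None = None,
    size: int = 224,
    resize_to: int = 256,
) -> np.ndarray:
    """Resize + crop + normalise to the 3x224x224 input contract.

    Training mode takes a seeded random crop after resizing the shorter side
    to ``resize_to``; eval mode takes the centre crop and is seed-independent.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    w, h = image.size
    if w < 1 or h < 1:
        raise ValueError("image must be at least 1x1 pixels")
    scale = resize_to / min(w, h)
    new_w, new_h = max(size, round(w * scale)), max(size, round(h * scale))
    image = image.resize((new_w, new_h), Image.BILINEAR)
    if mode == "train":
        rng = np.random.default_rng(seed)
        left = int(rng.integers(0, new_w - size + 1))
        top = int(rng.integers(0, new_h - size + 1))
    else:
        left, top = (new_w - size) // 2, (new_h - size) // 2
    image = image.crop((left, top, left + size, top + size))
    arr = np.asarray(image, dtype=np.float64) / 255.0  # HWC in [0,1]
    arr = arr.transpose(2, 0, 1)
    if mean is not None:
        arr = arr - np.asarray(mean, dtype=np.float64).reshape(3, 1, 1)
    if std is not None:
        arr = arr / np.asarray(std, dtype=np.float64).reshape(3, 1, 1)
    if not np.all(np.isfinite(arr)):
        raise ValueError("preprocessed image contains non-finite values")
    return arr
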
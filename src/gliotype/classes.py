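"""Tissue classes used throughout the pipeline.

The classifier distinguishes seven tissue types: normal grey matter (GM),
normal white matter (WM), cerebrospinal fluid (CSF), vasogenic oedema (VO),
grade II glioma tissue (GII), grade IV glioma tissue (GIV) and necrosis (Ne).
The ordering below is fixed and used everywhere a probability vector or a
label volume is indexed by class: index 1 = GM ... index 7 = Ne (0 is
reserved for "unlabelled"/background in label volumes).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TissueClass:
    """One of the seven tissue types, with its stable 1-based label index."""

    name: str
    index: int

    def __post_init__(self):
        if self.name not in CLASS_NAMES:
            raise ValueError(f"unknown tissue class {self.name!r}")
        if not 1 <= self.index <= 7:
            raise ValueError("tissue class index must be in 1..7")


CLASS_NAMES = ("GM", "WM", "CSF", "VO", "GII", "GIV", "Ne")

#: The canonical ordered class set; position i corresponds to label index i+1.
CLASSES = tuple(TissueClass(name, i + 1) for i, name in enumerate(CLASS_NAMES))

#: name -> TissueClass
CLASS_BY_NAME = {c.name: c for c in CLASSES}

#: label index -> TissueClass
CLASS_BY_INDEX = {c.index: c for c in CLASSES}

N_CLASSES = len(CLASSES)

#: Classes considered "abnormal" for lesion extraction (oedema + tumour + necrosis).
ABNORMAL_NAMES = ("VO", "GII", "GIV", "Ne")

#: Channels entering the Bayesian classifier, in the order of the 4D feature space.
CLASSIFIER_CHANNELS = ("p", "q", "T2n", "PDn")

#: Channels entering the superpixel segmentation.
SUPERPIXEL_CHANNELS = ("PDn", "FLAIR", "p")


def class_index(name: str) -> int:
    """0-based position of a class name in the canonical ordering."""
    return CLASS_BY_NAME[name].index - 1
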
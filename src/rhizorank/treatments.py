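"""Treatment factor coding for greenhouse biofertilizer trials.

A treatment combines up to three factors applied to a crop: a biochar
amendment, one of two five-strain microbial consortia (MC-B or MC-C),
and granular arbuscular mycorrhizal fungi (AMF, *R. intraradices*).
Labels follow the field convention of joining the applied factors with
underscores — ``"Char_MC-C_AMF"`` — with the bare control written
``"Control"``.  The delivery route is implied by the factor
combination: a consortium applied together with char is delivered as
functionalized char; a consortium without char is seed-coated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Crop(str, Enum):
    WHEAT = "wheat"
    MAIZE = "maize"


class Consortium(str, Enum):
    NONE = "none"
    MC_B = "MC-B"
    MC_C = "MC-C"


class Delivery(str, Enum):
    NONE = "none"
    SEED_COATING = "seed_coating"
    FUNCTIONALIZED_CHAR = "functionalized_char"


@dataclass(frozen=True, order=True)
class Treatment:
    """One experimental condition of a trial.

    The canonical ``label`` and the ``delivery`` route are deterministic
    functions of the factor flags; they are computed, never stored
    independently, so the label parser and formatter are exact inverses.
    """

    crop: Crop
    char_present: bool = False
    consortium: Consortium = Consortium.NONE
    amf_present: bool = False

    @property
    def delivery(self) -> Delivery:
        if self.consortium is Consortium.NONE:
            return Delivery.NONE
        if self.char_present:
            return Delivery.FUNCTIONALIZED_CHAR
        return Delivery.SEED_COATING

    @property
    def label(self) -> str:
        parts = []
        if self.char_present:
            parts.append("Char")
        if self.consortium is not Consortium.NONE:
            parts.append(self.consortium.value)
        if self.amf_present:
            parts.append("AMF")
        return "_".join(parts) if parts else "Control"

    @classmethod
    def from_label(cls, label: str, crop: Crop | str = Crop.WHEAT) -> "Treatment":
        """Parse a canonical label such as ``"Char_MC-B_AMF"``."""
        crop = Crop(crop)
        if label == "Control":
            return cls(crop=crop)
        char_present = False
        consortium = Consortium.NONE
        amf_present = False
        for part in label.split("_"):
            if part == "Char" and not char_present:
                char_present = True
            elif part in ("MC-B", "MC-C") and consortium is Consortium.NONE:
                consortium = Consortium(part)
            elif part == "AMF" and not amf_present:
                amf_present = True
            else:
                raise ValueError(f"unrecognized treatment label {label!r}")
        return cls(crop=crop, char_present=char_present,
                   consortium=consortium, amf_present=amf_present)


#: Treatment labels of the packaged wheat study, in table order.
WHEAT_LABELS: tuple[str, ...] = (
    "Control", "Char", "AMF", "Char_AMF",
    "MC-B", "MC-C", "MC-B_AMF", "MC-C_AMF",
    "Char_MC-B", "Char_MC-C", "Char_MC-B_AMF", "Char_MC-C_AMF",
)

#: Treatment labels of the packaged maize study, in table order.
MAIZE_LABELS: tuple[str, ...] = (
    "Control", "Char", "AMF", "Char_AMF",
    "Char_MC-B", "Char_MC-B_AMF", "Char_MC-C", "Char_MC-C_AMF",
)


def study_labels(crop: Crop | str) -> tuple[str, ...]:
    return WHEAT_LABELS if Crop(crop) is Crop.WHEAT else MAIZE_LABELS
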
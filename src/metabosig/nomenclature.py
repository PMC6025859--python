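"""Biocrates-style lysoPC/PC metabolite nomenclature.

The targeted panel measures three glycerophospholipid classes:

* ``lysoPC``  -- lysophosphatidylcholines, acyl ("lysoPC a C16:0")
* ``PCaa``    -- diacyl-phosphatidylcholines ("PC aa C32:3")
* ``PCae``    -- acyl-alkyl-phosphatidylcholines ("PC ae C38:0")

Names encode the summed acyl-chain carbon count and number of double
bonds as ``Cx:y``.  Two dialects are accepted: the spaced Biocrates
export form (``PC aa C32:3``) and the compact form (``PCaaC32:3``).
The compact form is canonical throughout this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["MetaboliteInfo", "classify_metabolite_name", "LIPID_CLASSES"]

LIPID_CLASSES = ("lysoPC", "PCaa", "PCae")

_NAME_RE = re.compile(
    r"^\s*(?:(?P<lyso>lyso\s*PC\s*a)|PC\s*(?P<pc>aa|ae))\s*"
    r"C\s*(?P<carbons>\d+)\s*:\s*(?P<bonds>\d+)\s*$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class MetaboliteInfo:
    """A parsed panel metabolite: lipid class, carbons and double bonds."""

    name: str
    lipid_class: str
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.carbons < 0 or self.double_bonds < 0:
            raise ValueError("carbons and double_bonds must be >= 0")

    @classmethod
    def from_name(cls, name: str) -> "MetaboliteInfo":
        return classify_metabolite_name(name)

    @property
    def canonical(self) -> str:
        prefix = "lysoPCa" if self.lipid_class == "lysoPC" else self.lipid_class
        return f"{prefix}C{self.carbons}:{self.double_bonds}"


class MetaboliteNameError(ValueError):
    """Raised for names that are not valid lysoPC/PCaa/PCae labels."""


def classify_metabolite_name(name: str) -> MetaboliteInfo:
    """Parse a metabolite label into :class:`MetaboliteInfo`.

    Accepts both the compact (``PCaaC32:3``) and spaced (``PC aa C32:3``)
    dialects; the returned ``name`` is always the canonical compact form,
    so ``classify_metabolite_name(x).canonical`` round-trips.

    Raises
    ------
    MetaboliteNameError
        If the class prefix is unrecognized or the ``Cx:y`` tail is
        malformed.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise MetaboliteNameError(f"unrecognized metabolite name: {name!r}")
    if m.group("lyso"):
        lipid_class = "lysoPC"
    else:
        lipid_class = "PC" + m.group("pc").lower()
    info = MetaboliteInfo(
        name="",  # placeholder, replaced with canonical below
        lipid_class=lipid_class,
        carbons=int(m.group("carbons")),
        double_bonds=int(m.group("bonds")),
    )
    return MetaboliteInfo(info.canonical, lipid_class, info.carbons, info.double_bonds)


def is_metabolite_name(name: str) -> bool:
    """True if *name* parses as a panel metabolite label."""
    try:
        classify_metabolite_name(name)
    except MetaboliteNameError:
        return False
    return True
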
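"""Nearest-neighbor parameter tables, loaded from versioned TSV data files.

The tables use the conventional stack notation ``XY/ZW``: top strand
dinucleotide 5'->3' over bottom strand dinucleotide 3'->5'.  A stack and
its 180-degree rotation (``XY/ZW`` vs ``WZ/YX``) describe the same physical
structure; Watson-Crick stacks are stored in both orientations, mismatch
stacks are stored WC-column-first and resolved by rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .errors import ThermoError

R_GAS = 1.9872  # cal/(mol*K)

WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_wc(top: str, bottom: str) -> bool:
    """True iff top/bottom is a Watson-Crick pair."""
    return (top, bottom) in WC_PAIRS


def rotate_stack(key: str) -> str:
    """180-degree rotation of a stack key: XY/ZW -> WZ/YX."""
    top, bottom = key.split("/")
    return bottom[::-1] + "/" + top[::-1]


def _read_tsv(name: str) -> tuple[dict[str, tuple[float, float]], str]:
    version = ""
    table: dict[str, tuple[float, float]] = {}
    text = resources.files("plexscreen.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "version:" in line:
                version = line.split("version:", 1)[1].strip()
            continue
        fields = line.split("\t")
        if fields[0] in ("stack", "loop_size"):
            continue
        second = float(fields[2]) if len(fields) > 2 else 0.0
        table[fields[0]] = (float(fields[1]), second)
    return table, version


@dataclass(frozen=True)
class NNParameterTable:
    """Unified Watson-Crick + single-internal-mismatch NN parameters.

    Values are (dH kcal/mol, dS cal/(mol*K)) at the 1 M NaCl reference
    state; salt dependence is applied downstream as an entropy correction.
    """

    wc: dict[str, tuple[float, float]]
    mismatch: dict[str, tuple[float, float]]
    init_at: tuple[float, float]
    init_gc: tuple[float, float]
    sym: tuple[float, float]
    version: str

    def stack(self, top: str, bottom: str) -> tuple[float, float]:
        """Look up the stack with top/bottom dinucleotides (3'->5' bottom)."""
        key = top + "/" + bottom
        for k in (key, rotate_stack(key)):
            if k in self.wc:
                return self.wc[k]
            if k in self.mismatch:
                return self.mismatch[k]
        raise ThermoError(f"no nearest-neighbor parameters for stack {key}")

    def initiation(self, top: str, bottom: str) -> tuple[float, float]:
        """Initiation term for one terminal base pair (must be WC)."""
        if not is_wc(top, bottom):
            raise ThermoError(f"terminal pair {top}/{bottom} is not Watson-Crick")
        return self.init_gc if top in "GC" else self.init_at


@dataclass(frozen=True)
class HairpinLoopTable:
    """Hairpin loop initiation dG37 by loop size (entropic penalty).

    Sizes between tabulated entries are interpolated linearly; sizes above
    the largest entry follow the Jacobson-Stockmayer form
    dG(n) = dG(max) + 1.75 * R * T * ln(n / max) at 310.15 K.
    """

    dg37: dict[int, float]
    version: str

    def loop_dg37(self, size: int) -> float:
        if size < min(self.dg37):
            raise ThermoError(f"hairpin loop of size {size} below minimum")
        if size in self.dg37:
            return self.dg37[size]
        sizes = sorted(self.dg37)
        if size > sizes[-1]:
            top = sizes[-1]
            return self.dg37[top] + 1.75 * R_GAS * 310.15 / 1000.0 * math.log(
                size / top
            )
        lo = max(s for s in sizes if s < size)
        hi = min(s for s in sizes if s > size)
        frac = (size - lo) / (hi - lo)
        return self.dg37[lo] + frac * (self.dg37[hi] - self.dg37[lo])


@lru_cache(maxsize=1)
def default_nn_table() -> NNParameterTable:
    wc_raw, version_wc = _read_tsv("nn_watson_crick.tsv")
    mm_raw, version_mm = _read_tsv("nn_internal_mismatch.tsv")
    init_at = wc_raw.pop("init_A/T")
    init_gc = wc_raw.pop("init_G/C")
    sym = wc_raw.pop("sym")
    return NNParameterTable(
        wc=wc_raw,
        mismatch=mm_raw,
        init_at=init_at,
        init_gc=init_gc,
        sym=sym,
        version=f"{version_wc}+{version_mm}",
    )


@lru_cache(maxsize=1)
def default_loop_table() -> HairpinLoopTable:
    raw, version = _read_tsv("hairpin_loops.tsv")
    return HairpinLoopTable({int(float(k)): v[0] for k, v in raw.items()}, version)


def complement_acgt(seq: str) -> str:
    """Base-wise complement of an ACGT string (no reversal)."""
    try:
        return "".join(_COMPLEMENT[c] for c in seq)
    except KeyError as exc:
        raise ThermoError(f"non-ACGT base {exc.args[0]!r} in {seq!r}") from None
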
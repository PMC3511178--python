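"""Melting-temperature and cycling-parameter formulas for PCR design.

Four classic estimates are implemented:

* the Wallace rule ``Tm = 2(A+T) + 4(G+C)`` for short oligos,
* the nearest-neighbor duplex Tm
  ``Tm(degC) = dH / (dS + R ln(c/4)) + salt_correction - 273.15``
  with dH/dS summed over dinucleotide stacks plus initiation terms,
* the product melting temperature
  ``Tm = 81.5 + 0.41 (%GC) + 16.6 log10[K+] - 675/length``,
* the annealing temperature ``Ta = 0.3 Tm(primer) + 0.7 Tm(product) - 14.9``,

plus the rule-of-thumb extension time of 1000 bases per minute.

Two monovalent-salt corrections are available for the nearest-neighbor Tm:
``"schildkraut"`` (the additive ``16.6 log10[K+]`` term, the default) and
``"owczarzy"`` (the reciprocal-Kelvin correction used by common primer-design
software). At 50 mM monovalent cation the additive term depresses Tm by about
7-8 degC relative to typical software output; see docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Tuple

from .seq import SequenceError, _as_residues, gc_percent

GAS_CONSTANT_R = 1.987  # cal / (K mol)


def _load_nn_table() -> dict:
    with resources.files("rflpsim.data").joinpath("nn_table.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters for Tm calculations.

    primer_concentration_c
        Total single-strand oligo concentration in mol/L (the ``c`` in the
        nearest-neighbor formula; for non-self-complementary duplexes the
        effective annealing concentration is ``c/4``). Default 0.25 uM, a
        typical PCR primer concentration.
    potassium_mM
        Monovalent cation concentration in mM. Default 50 (standard PCR
        buffer KCl).
    salt_correction
        ``"schildkraut"`` for the additive 16.6 log10[K+] term or
        ``"owczarzy"`` for the reciprocal-Kelvin GC-dependent correction.
    """

    primer_concentration_c: float = 0.25e-6
    potassium_mM: float = 50.0
    gas_constant_R: float = GAS_CONSTANT_R
    salt_correction: str = "schildkraut"
    nn_table: dict = field(default_factory=_load_nn_table)

    def __post_init__(self) -> None:
        if self.primer_concentration_c <= 0:
            raise ValueError("primer_concentration_c must be > 0")
        if self.potassium_mM <= 0:
            raise ValueError("potassium_mM must be > 0")
        if self.salt_correction not in ("schildkraut", "owczarzy"):
            raise ValueError(f"unknown salt_correction {self.salt_correction!r}")


DEFAULT_PARAMS = ThermoParams()


@dataclass(frozen=True)
class PrimerThermo:
    """Per-primer thermodynamic summary (length, GC%, Wallace and NN Tm)."""

    name: str
    length: int
    gc_pct: float
    tm_wallace: float
    tm_nn: float


def _require_unambiguous(seq: str, op: str) -> str:
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise SequenceError(
                f"{op} requires A/C/G/T only; degenerate code {ch!r} at position {i}"
            )
    return seq


def tm_wallace(primer_seq) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C), in degC."""
    s = _require_unambiguous(_as_residues(primer_seq), "tm_wallace")
    at = sum(1 for ch in s if ch in "AT")
    gc = len(s) - at
    return float(2 * at + 4 * gc)


def duplex_enthalpy_entropy(primer_seq, params: ThermoParams = DEFAULT_PARAMS
                            ) -> Tuple[float, float]:
    """Sum nearest-neighbor stack and initiation terms.

    Returns (dH in kcal/mol, dS in cal/(mol K)).
    """
    s = _require_unambiguous(_as_residues(primer_seq), "nearest-neighbor Tm")
    if len(s) < 2:
        raise SequenceError("nearest-neighbor Tm requires length >= 2")
    stacks: Dict[str, list] = params.nn_table["stacks"]
    init: Dict[str, list] = params.nn_table["initiation"]
    dh, ds = 0.0, 0.0
    for end in (s[0], s[-1]):
        key = "GC" if end in "GC" else "AT"
        dh += init[key][0]
        ds += init[key][1]
    for i in range(len(s) - 1):
        pair = s[i:i + 2]
        if pair not in stacks:
            raise SequenceError(f"nn_table has no entry for stack {pair!r}")
        dh += stacks[pair][0]
        ds += stacks[pair][1]
    return dh, ds


def tm_nearest_neighbor(primer_seq, params: ThermoParams = DEFAULT_PARAMS) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    With the default ``schildkraut`` correction this evaluates
    ``dH / (dS + R ln(c/4)) + 16.6 log10([K+] in M) - 273.15``.
    """
    s = _as_residues(primer_seq)
    dh, ds = duplex_enthalpy_entropy(s, params)
    c = params.primer_concentration_c
    tm_kelvin = (dh * 1000.0) / (ds + params.gas_constant_R * math.log(c / 4.0))
    k_molar = params.potassium_mM / 1000.0
    if params.salt_correction == "schildkraut":
        return tm_kelvin + 16.6 * math.log10(k_molar) - 273.15
    # owczarzy: reciprocal-Kelvin correction, GC-fraction dependent
    f_gc = gc_percent(s) / 100.0
    inv = (1.0 / tm_kelvin
           + (4.29 * f_gc - 3.95) * 1e-5 * math.log(k_molar)
           + 9.40e-6 * math.log(k_molar) ** 2)
    return 1.0 / inv - 273.15


def tm_product(gc_pct: float, product_length: int, potassium_mM: float = 50.0) -> float:
    """Melting temperature of a PCR product in degC.

    ``81.5 + 0.41 (%GC) + 16.6 log10([K+] in M) - 675/length``.
    """
    if product_length <= 0:
        raise ValueError("product_length must be > 0")
    if not 0.0 <= gc_pct <= 100.0:
        raise ValueError("gc_pct must be in [0, 100]")
    if potassium_mM <= 0:
        raise ValueError("potassium_mM must be > 0")
    return (81.5 + 0.41 * gc_pct + 16.6 * math.log10(potassium_mM / 1000.0)
            - 675.0 / product_length)


def annealing_temperature(tm_primer: float, tm_product_: float) -> float:
    """Recommended annealing temperature: 0.3 Tm(primer) + 0.7 Tm(product) - 14.9."""
    if not (math.isfinite(tm_primer) and math.isfinite(tm_product_)):
        raise ValueError("Tm inputs must be finite")
    return 0.3 * tm_primer + 0.7 * tm_product_ - 14.9


def extension_time(product_length: int) -> float:
    """Extension time in seconds at ~1000 bases incorporated per minute."""
    if product_length <= 0:
        raise ValueError("product_length must be > 0")
    return 60.0 * product_length / 1000.0


def primer_thermo(name: str, sequence, params: ThermoParams = DEFAULT_PARAMS
                  ) -> PrimerThermo:
    """Length, GC%, Wallace Tm and nearest-neighbor Tm for one primer."""
    s = _as_residues(sequence)
    return PrimerThermo(
        name=name,
        length=len(s),
        gc_pct=gc_percent(s),
        tm_wallace=tm_wallace(s),
        tm_nn=tm_nearest_neighbor(s, params),
    )
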
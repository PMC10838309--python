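"""Nearest-neighbor hybridization thermodynamics.

Two quantities drive the pipeline:

* :func:`melting_temperature` — unified nearest-neighbor Tm of a probe with
  monovalent-salt correction (entropic, 0.368·(N-1)·ln[Na+]) and a linear
  formamide correction of 0.65 °C per percent formamide.
* :func:`duplex_probability` — a two-state (bound/unbound) equilibrium model
  of a probe hybridized to an aligned genomic site.  ΔG° at the hybridization
  temperature is accumulated over nearest-neighbor stacks spanning
  consecutive matched columns; every mismatched or gapped column incurs a
  destabilizing penalty (+1.0 kcal/mol at the 69.5 °C reference, implemented
  entropically so that duplex probability is non-increasing in temperature
  for every alignment pair).  The fraction duplexed at equal strand
  concentrations follows from the mass-action quadratic.

Parameters ship in ``data/nn_params.tsv`` (ΔH kcal/mol, ΔS cal/mol·K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

R_GAS = 1.987204258  # cal / (mol K)
_T_REF = 69.5 + 273.15  # reference temperature anchoring the mismatch penalty
MISMATCH_PENALTY_KCAL = 1.0  # free-energy penalty per mismatched/gapped column at T_REF
_DS_PENALTY = -MISMATCH_PENALTY_KCAL * 1000.0 / _T_REF  # cal/(mol K), < 0


class ThermoError(ValueError):
    pass


@dataclass(frozen=True)
class ThermoModel:
    """Hybridization conditions for duplex-probability scoring.

    Defaults reflect a standard oligo FISH hybridization: 69.5 °C effective
    temperature, 0.39 M monovalent salt, no divalents, equal strand
    concentrations of 1 µM.  Formamide stringency is encoded in the
    effective temperature here; the separate formamide term applies only to
    probe-Tm windowing.
    """

    temperature_celsius: float = 69.5
    sodium_molar: float = 0.39
    magnesium_molar: float = 0.0
    formamide_percent: float = 0.0
    strand_concentration: float = 1e-6

    def __post_init__(self):
        if not math.isfinite(self.temperature_celsius):
            raise ThermoError("temperature must be finite")
        for name in ("sodium_molar", "magnesium_molar", "strand_concentration"):
            if getattr(self, name) < 0:
                raise ThermoError(f"{name} must be >= 0")


@lru_cache(maxsize=1)
def nn_parameters() -> dict[str, tuple[float, float]]:
    """Load the nearest-neighbor ΔH/ΔS table shipped with the package."""
    params: dict[str, tuple[float, float]] = {}
    text = (resources.files("repeatprobe") / "data" / "nn_params.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split("\t")
        params[key] = (float(dh), float(ds))
    return params


def _init_key(base: str) -> str:
    return "init_GC" if base in "GC" else "init_AT"


def melting_temperature(
    seq: str,
    sodium_molar: float = 0.39,
    formamide_percent: float = 50.0,
    strand_concentration: float = 1e-6,
) -> float:
    """Formamide-adjusted nearest-neighbor melting temperature in °C.

    ``strand_concentration`` is the per-strand molar concentration (equal,
    non-self-complementary strands assumed, so the CT/4 rule applies).
    """
    if len(seq) < 2:
        raise ThermoError("sequence must have length >= 2")
    params = nn_parameters()
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in params:
            raise ThermoError(f"invalid base in sequence at position {i}: {pair!r}")
        h, s = params[pair]
        dh += h
        ds += s
    for base in (seq[0], seq[-1]):
        h, s = params[_init_key(base)]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(sodium_molar)
    tm_kelvin = dh * 1000.0 / (ds + R_GAS * math.log(strand_concentration / 2.0))
    return tm_kelvin - 273.15 - 0.65 * formamide_percent


def duplex_free_energy(
    probe_row: str, target_row: str, model: ThermoModel
) -> float:
    """ΔG° (kcal/mol) of the aligned duplex at the model temperature.

    Columns are matched when the two rows carry the same A/C/G/T character
    (the target row is given in the probe's reading frame, so identity means
    Watson-Crick pairing of probe against the genomic site).  Stacks span
    consecutive matched columns; every other column adds the destabilizing
    penalty.
    """
    if len(probe_row) != len(target_row):
        raise ThermoError("aligned rows must have equal length")
    params = nn_parameters()
    t_kelvin = model.temperature_celsius + 273.15
    matched = [
        a == b and a in "ACGT"
        for a, b in zip(probe_row, target_row)
    ]
    dh = ds = 0.0
    n_stacks = 0
    for i in range(len(matched) - 1):
        if matched[i] and matched[i + 1]:
            h, s = params[probe_row[i] + probe_row[i + 1]]
            dh += h
            ds += s
            n_stacks += 1
    match_positions = [i for i, m in enumerate(matched) if m]
    if match_positions:
        for i in (match_positions[0], match_positions[-1]):
            h, s = params[_init_key(probe_row[i])]
            dh += h
            ds += s
    if model.sodium_molar > 0 and n_stacks:
        ds += 0.368 * n_stacks * math.log(model.sodium_molar)
    n_penalized = len(matched) - len(match_positions)
    ds += _DS_PENALTY * n_penalized
    return dh - t_kelvin * ds / 1000.0


def duplex_probability(
    probe_row: str, target_row: str, model: ThermoModel | None = None
) -> float:
    """Two-state equilibrium probability that the aligned pair is duplexed.

    Solves the mass-action quadratic for equal strand concentrations c:
    with Kc = K·c, the duplexed fraction is
    ``(2Kc + 1 - sqrt(4Kc + 1)) / (2Kc)``, clamped to [0, 1].
    """
    if model is None:
        model = ThermoModel()
    dg = duplex_free_energy(probe_row, target_row, model)
    t_kelvin = model.temperature_celsius + 273.15
    exponent = -dg * 1000.0 / (R_GAS * t_kelvin)
    kc = math.exp(min(exponent, 700.0)) * model.strand_concentration
    if kc <= 0.0:
        return 0.0
    f = (2.0 * kc + 1.0 - math.sqrt(4.0 * kc + 1.0)) / (2.0 * kc)
    return min(max(f, 0.0), 1.0)
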
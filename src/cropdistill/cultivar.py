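"""Cultivar parameter set for the rice growth simulator.

Parameters are stored in a flat ``key: value`` text config so a parameter
file can be versioned and swapped per cultivar without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class CultivarParams:
    """All constants of the simulator for one cultivar.

    Phenology: ``Gv`` minimum days to heading, ``A`` temperature response
    slope (°C⁻¹), ``Th`` half-rate temperature (°C), ``DVI_star`` DVI at
    photoperiod-sensitivity onset, ``Lc`` critical day length (h), ``Bp``
    photoperiod constant (h⁻¹), ``Gr`` minimum grain-filling days, ``Kr``
    (°C⁻¹) and ``Tcr`` (°C) grain-filling temperature response.

    Growth: ``C0`` conversion efficiency of absorbed short-wave radiation
    at 330 ppm CO2 (g DM MJ⁻¹), ``Rm`` CO2 response asymptote, ``Kc`` (ppm),
    ``Cf``/``Bf``/``tf`` grain-filling efficiency decline constants.

    Yield formation: ``hm`` maximum harvest index, ``Kh`` harvest-index
    development constant, ``gamma0``/``Kq``/``aq`` cool-summer sterility
    response, all sterilities handled as fractions in [0, 1].

    Canopy surrogate: ``LAI_max`` (m² m⁻²), ``k_beer`` light extinction
    coefficient, ``lai_rise_exp`` and ``lai_decline_rate`` shape constants
    of the developmental LAI curve.
    """

    Gv: float
    A: float
    Th: float
    DVI_star: float
    Lc: float
    Bp: float
    Gr: float
    Kr: float
    Tcr: float
    C0: float
    Rm: float
    Kc: float
    Cf: float
    Bf: float
    tf: float
    hm: float
    Kh: float
    gamma0: float
    Kq: float
    aq: float
    LAI_max: float
    k_beer: float
    lai_rise_exp: float
    lai_decline_rate: float

    def __post_init__(self) -> None:
        if self.Gv <= 0 or self.Gr <= 0:
            raise ValueError("Gv and Gr must be positive day counts")
        if not 0 < self.hm <= 1:
            raise ValueError("hm must be in (0, 1]")
        if not 0 < self.Lc < 24:
            raise ValueError("Lc must be in (0, 24) hours")
        if self.aq <= 0:
            raise ValueError("aq must be positive")
        if self.k_beer <= 0:
            raise ValueError("k_beer must be positive")


_FIELD_NAMES = tuple(f.name for f in fields(CultivarParams))


def load_params(path: str | Path) -> CultivarParams:
    """Parse a flat ``key: value`` parameter file ('#' starts a comment)."""
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, sep, val = line.partition(":")
        if not sep:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key = key.strip()
        if key not in _FIELD_NAMES:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        values[key] = float(val)
    missing = [k for k in _FIELD_NAMES if k not in values]
    if missing:
        raise ValueError(f"{path}: missing parameters {missing}")
    return CultivarParams(**values)


def save_params(params: CultivarParams, path: str | Path) -> None:
    lines = [f"{name}: {getattr(params, name)!r}" for name in _FIELD_NAMES]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_params() -> CultivarParams:
    """Packaged Koshihikari-like parameter set (see the file's provenance notes)."""
    ref = resources.files("cropdistill.data").joinpath("koshihikari.txt")
    with resources.as_file(ref) as path:
        return load_params(path)
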
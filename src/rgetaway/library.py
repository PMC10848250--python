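"""The 15-compound API library used to build the PVPVA dispersibility model.

Single-conformation R3m values (CORINA-predicted 3D structures),
crystallographic densities from the corresponding CCDC entries, and the
experimentally observed melt-quench dispersibility in PVPVA. These are the
published inputs of the model; the MD-derived conformer distributions are
not reproducible here and are emulated by :mod:`rgetaway.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LibraryEntry", "API_LIBRARY"]


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    r3m: float                              # CORINA single-conformation value
    crystallographic_density: float | None  # g/cm^3, CCDC structure
    disperses: bool                         # forms an ASD in PVPVA (melt-quench)
    ccdc_refcode: str | None = None


API_LIBRARY: list[LibraryEntry] = [
    LibraryEntry("propranolol", 0.342, 1.164, False, "IMITON"),
    LibraryEntry("cimetidine", 0.403, 1.312, False, "CIMETD"),
    LibraryEntry("melatonin", 0.407, 1.276, False, "MELATN01"),
    LibraryEntry("terfenadine", 0.561, 1.130, False, "EWEMIF"),
    LibraryEntry("cloperastine", 0.562, None, False, None),
    LibraryEntry("nifedipine", 0.568, 1.382, False, "BICCIZ03"),
    LibraryEntry("quinidine", 0.593, 1.234, False, "BOMDUC"),
    LibraryEntry("sulfanilamide", 0.595, 1.514, False, "SULAMD03"),
    LibraryEntry("tolbutamide", 0.687, 1.252, True, "ZZZPUS18"),
    LibraryEntry("indomethacin", 0.737, 1.372, True, "INDMET"),
    LibraryEntry("ketoconazole", 0.814, 1.400, True, "KCONAZ"),
    LibraryEntry("itraconazole", 0.872, 1.360, True, "TEHZIP"),
    LibraryEntry("chlorpropamide", 0.927, 1.450, True, "BEDMIG10"),
    LibraryEntry("felodipine", 0.964, 1.451, True, "DONTIJ"),
    LibraryEntry("bicalutamide", 1.001, 1.554, True, "JAYCES"),
]
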
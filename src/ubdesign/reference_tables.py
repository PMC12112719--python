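"""Published benchmark tables for the HER3 binder-design study.

These small printed tables are *inputs* to the package's arithmetic and
classification checks: measured surface-plasmon-resonance K_D values (nM)
for the computationally designed candidates (``COMPUTATIONAL_DESIGNS``) and
the phage-display hits (``EXPERIMENTAL_HITS``), the per-target class counts
of the training library (``LIBRARY_CLASS_COUNTS``), and the band sizes
assigned by the molecular-dynamics stage of the computational funnel.

``None`` marks constructs that were not expressed or not determined;
``"NB"`` marks constructs with no detectable binding.
"""

from __future__ import annotations

from .seq_data import classify_binder

#: Lab-scale SPR K_D (nM) of the 12 computationally designed candidates.
COMPUTATIONAL_DESIGNS: dict[str, float | str | None] = {
    "Comp-1": None,
    "Comp-2": 2061.0,
    "Comp-3": None,
    "Comp-4": "NB",
    "Comp-5": "NB",
    "Comp-6": 10000.0,
    "Comp-7": 462.0,
    "Comp-8": 5381.0,
    "Comp-9": 29.8,
    "Comp-10": 1488.0,
    "Comp-11": 63.2,
    "Comp-12": "NB",
}

#: SPR K_D (nM) of the four in vitro selected hits: (µ-scale, lab scale).
EXPERIMENTAL_HITS: dict[str, tuple[float, float]] = {
    "Exp-1": (2.5, 5.4),
    "Exp-2": (8.6, 19.4),
    "Exp-3": (8.7, 26.4),
    "Exp-4": (5.9, 17.1),
}

#: Training-library class counts per target: {target: {SB, MB, WB}}.
LIBRARY_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "HER2": {"SB": 72, "MB": 59, "WB": 16},
    "FINC_EDB": {"SB": 36, "MB": 32, "WB": 18},
    "Others": {"SB": 127, "MB": 208, "WB": 191},
}

#: Candidates per predicted band after the MD stage of the funnel.
MD_STAGE_BAND_SIZES: dict[str, int] = {"NB/WB": 6, "MB": 9, "SB": 11}


def numeric_kds(table: dict[str, float | str | None]) -> dict[str, float]:
    """Entries of a K_D table with a measurable numeric affinity."""
    return {k: v for k, v in table.items() if isinstance(v, (int, float))}


def classify_table(table: dict[str, float | str | None]) -> dict[str, str]:
    """Binder class per candidate; non-expressed entries are dropped and
    'NB' annotations pass through unchanged."""
    out: dict[str, str] = {}
    for name, kd in table.items():
        if kd is None:
            continue
        out[name] = kd if kd == "NB" else classify_binder(float(kd))
    return out
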
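"""The 25-channel IFCN scalp montage and the electrode sets used throughout.

The montage is the conventional 10-20 array extended with an inferior
temporal chain (F9/F10, T9/T10, P9/P10), recommended by the IFCN for
routine practice because it improves temporal-lobe coverage without
moving to high-density recordings.
"""

from __future__ import annotations

#: The 25 electrode labels, in acquisition order.
MONTAGE_25: tuple[str, ...] = (
    "Fp1", "Fp2", "F9", "F10", "T9", "T10", "P9", "P10",
    "F7", "F8", "T7", "T8", "P7", "P8", "F3", "F4",
    "C3", "C4", "P3", "P4", "O1", "O2", "Fz", "Cz", "Pz",
)

#: 16-node frontotemporal subnetwork.
FRONTOTEMPORAL: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F9", "F10", "T9", "T10",
    "P9", "P10", "F7", "F8", "T7", "T8", "P7", "P8",
)

#: Left / right frontal electrode triples used by the laterality index.
LEFT_FRONTAL: tuple[str, ...] = ("Fp1", "F3", "F7")
RIGHT_FRONTAL: tuple[str, ...] = ("Fp2", "F4", "F8")

#: Lateral halves of the frontotemporal set (odd = left, even = right),
#: ordered from the temporal chain outward — the order in which a shared
#: oscillator is staggered across the chain in the synthetic cohort.
LEFT_FRONTOTEMPORAL: tuple[str, ...] = ("T7", "T9", "F7", "F9", "P7", "P9", "Fp1", "F3")
RIGHT_FRONTOTEMPORAL: tuple[str, ...] = ("T8", "T10", "F8", "F10", "P8", "P10", "Fp2", "F4")

#: Canonical frequency bands (Hz).  "full" is the broadband analysis band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 45.0),
    "full": (1.0, 45.0),
}


def check_labels(labels, universe=MONTAGE_25) -> None:
    """Raise ``ValueError`` naming any label not in *universe* (case-sensitive)."""
    unknown = [lab for lab in labels if lab not in universe]
    if unknown:
        raise ValueError(f"unknown electrode label(s): {unknown!r}; montage is {list(universe)}")
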
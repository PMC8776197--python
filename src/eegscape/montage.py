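"""Electrode montage: 32-channel 10-20 layout, references, and feature-channel pairings.

The decoding features need three channel groupings on top of the raw
32-electrode cap:

* the 29-channel *feature subset* (everything except the two mastoid
  references TP9/TP10 and the midline occipital Oz), which fixes the
  per-band dimensionality of MAS/PSD/DE at 29;
* 13 mirror-image left-right electrode pairs, which give the hemispheric
  asymmetry features DASM and RASM their dimensionality;
* 11 frontal-posterior pairs along matched lateral lines, which give the
  caudality feature DCAU its dimensionality.

The default layout below is the standard 32-channel LiveAmp/actiCAP cap.
Any montage satisfying the same cardinality and containment rules can be
substituted through the config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Nominal 2-D scalp coordinates (head seen from above, nose up):
# x < 0 left hemisphere, y > 0 anterior.  Units are arbitrary (unit head radius).
_COORDS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.55, 0.67), "Fz": (0.0, 0.72),
    "F4": (0.55, 0.67), "F8": (0.81, 0.59),
    "FT9": (-0.98, 0.32), "FC5": (-0.78, 0.34), "FC1": (-0.37, 0.38),
    "FC2": (0.37, 0.38), "FC6": (0.78, 0.34), "FT10": (0.98, 0.32),
    "T7": (-1.0, 0.0), "C3": (-0.71, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.71, 0.0), "T8": (1.0, 0.0),
    "TP9": (-1.05, -0.33), "CP5": (-0.78, -0.34), "CP1": (-0.37, -0.38),
    "CP2": (0.37, -0.38), "CP6": (0.78, -0.34), "TP10": (1.05, -0.33),
    "P7": (-0.81, -0.59), "P3": (-0.55, -0.67), "Pz": (0.0, -0.72),
    "P4": (0.55, -0.67), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}

_DEFAULT_ELECTRODES = [
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "FC1", "FC2", "FC5", "FC6", "FT9", "FT10",
    "C3", "C4", "Cz", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6", "TP9", "TP10",
    "P3", "P4", "P7", "P8", "Pz",
    "O1", "O2", "Oz",
]

_DEFAULT_LR_PAIRS = [
    ("Fp1", "Fp2"), ("F3", "F4"), ("F7", "F8"),
    ("FC1", "FC2"), ("FC5", "FC6"), ("FT9", "FT10"),
    ("C3", "C4"), ("T7", "T8"),
    ("CP1", "CP2"), ("CP5", "CP6"),
    ("P3", "P4"), ("P7", "P8"), ("O1", "O2"),
]

_DEFAULT_FP_PAIRS = [
    ("Fp1", "O1"), ("Fp2", "O2"),
    ("F3", "P3"), ("F4", "P4"), ("F7", "P7"), ("F8", "P8"),
    ("FC1", "CP1"), ("FC2", "CP2"), ("FC5", "CP5"), ("FC6", "CP6"),
    ("Fz", "Pz"),
]


@dataclass(frozen=True)
class Montage:
    """Electrode inventory plus the channel groupings the features rely on.

    Attributes
    ----------
    electrodes
        Ordered electrode labels; this is the channel order of raw recordings.
    coords
        2-D scalp position per label (x left-negative, y anterior-positive).
    reference_labels
        The (left, right) mastoid pair used for re-referencing.
    feature_channels
        Ordered 29-label subset on which all features are computed.
    lr_pairs
        13 (left, right) mirror pairs for DASM/RASM.
    fp_pairs
        11 (frontal, posterior) pairs for DCAU.
    """

    electrodes: tuple[str, ...] = tuple(_DEFAULT_ELECTRODES)
    coords: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(_COORDS))
    reference_labels: tuple[str, str] = ("TP9", "TP10")
    feature_channels: tuple[str, ...] = tuple(
        ch for ch in _DEFAULT_ELECTRODES if ch not in ("TP9", "TP10", "Oz")
    )
    lr_pairs: tuple[tuple[str, str], ...] = tuple(_DEFAULT_LR_PAIRS)
    fp_pairs: tuple[tuple[str, str], ...] = tuple(_DEFAULT_FP_PAIRS)

    def channel_index(self, labels) -> np.ndarray:
        """Zero-based positions of ``labels`` in the electrode order.

        Raises
        ------
        KeyError
            If any label is not in the montage, naming the offender.
        """
        lookup = {ch: i for i, ch in enumerate(self.electrodes)}
        out = []
        for lab in labels:
            if lab not in lookup:
                raise KeyError(f"unknown electrode label: {lab!r}")
            out.append(lookup[lab])
        return np.asarray(out, dtype=int)

    def frontal_loading(self) -> np.ndarray:
        """Per-electrode blink topography weight, maximal at the frontopolar row.

        Derived from the anterior coordinate: weight = max(y, 0)^2, normalised
        to 1 at the most anterior electrode.  Used by the synthetic generator
        and by artifact-removal heuristics.
        """
        y = np.array([self.coords[ch][1] for ch in self.electrodes])
        w = np.clip(y, 0.0, None) ** 2
        return w / w.max()


def default_montage() -> Montage:
    """The packaged 32-channel default (standard LiveAmp actiCAP layout).

    TP9/TP10 serve as mastoid references and Oz is additionally excluded from
    the feature set, yielding 29 feature channels, 13 left-right pairs and 11
    frontal-posterior pairs.
    """
    return Montage()


def validate(montage: Montage) -> list[str]:
    """Check every montage invariant; return a list of human-readable violations.

    An empty list means the montage is internally consistent: correct
    cardinalities (29 feature channels, 13 left-right pairs, 11
    frontal-posterior pairs), containment of every pair member in the feature
    subset, exclusion of the reference labels, and left-right mirror symmetry
    of the lateral pairs.
    """
    v: list[str] = []
    elec = set(montage.electrodes)
    feat = set(montage.feature_channels)

    if len(montage.feature_channels) != 29:
        v.append(f"feature_channels cardinality is {len(montage.feature_channels)}, expected 29")
    if len(montage.lr_pairs) != 13:
        v.append(f"lr_pairs cardinality is {len(montage.lr_pairs)}, expected 13")
    if len(montage.fp_pairs) != 11:
        v.append(f"fp_pairs cardinality is {len(montage.fp_pairs)}, expected 11")
    if len(set(montage.electrodes)) != len(montage.electrodes):
        v.append("duplicate electrode labels")
    if not feat <= elec:
        v.append(f"feature channels not in electrode set: {sorted(feat - elec)}")
    for ref in montage.reference_labels:
        if ref not in elec:
            v.append(f"reference label {ref} not in electrode set")
        if ref in feat:
            v.append(f"reference label {ref} must not be a feature channel")
    for kind, pairs in (("lr_pairs", montage.lr_pairs), ("fp_pairs", montage.fp_pairs)):
        for a, b in pairs:
            for lab in (a, b):
                if lab not in feat:
                    v.append(f"{kind} member {lab} not in feature_channels")
    # mirror symmetry of lateral pairs: (x_left, y) should map to (-x, y)
    for a, b in montage.lr_pairs:
        if a in montage.coords and b in montage.coords:
            xa, ya = montage.coords[a]
            xb, yb = montage.coords[b]
            if xa >= 0:
                v.append(f"lr_pairs: left member {a} is not on the left hemisphere")
            if abs(xa + xb) > 1e-6 or abs(ya - yb) > 1e-6:
                v.append(f"lr_pairs: ({a},{b}) are not mirror images")
    for a, b in montage.fp_pairs:
        if a in montage.coords and b in montage.coords:
            if montage.coords[a][1] <= montage.coords[b][1]:
                v.append(f"fp_pairs: ({a},{b}) is not frontal-to-posterior")
    return v
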
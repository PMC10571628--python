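"""Aggregation of scalar maps over an eight-lobe cortical parcellation.

The eight lobes are orbitofrontal (OFC), lateral prefrontal (LPFC), medial
prefrontal (MPFC), lateral temporal (LTC), medial temporal (MTC),
somatomotor (SMC), parietal (PC) and occipital (OCC) cortex.  Parcels of a
label map (e.g. FreeSurfer aparc+aseg registered to the diffusion grid)
are grouped into lobes through an editable TSV lookup; the shipped default
groups Desikan-Killiany cortical parcels into the eight lobes and is a
plausible reconstruction, not a canonical definition.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ScalarMap, check_geometry

LOBES = ("OFC", "LPFC", "MPFC", "LTC", "MTC", "SMC", "PC", "OCC")


@dataclass
class LobeParcellation:
    """Integer label map plus a parcel-label -> lobe lookup.

    Labels mapped to the sentinel lobe ``"ignore"`` in the lookup are
    silently dropped; any other nonzero label absent from the lookup is an
    error unless ``allow_unlisted`` is set (then dropped with a warning).
    Background is label 0.
    """

    label_map: np.ndarray
    lobe_lookup: dict[int, str]
    affine: np.ndarray | None = None
    allow_unlisted: bool = False
    ignored: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if not np.issubdtype(self.label_map.dtype, np.integer):
            rounded = np.round(self.label_map)
            if not np.allclose(self.label_map, rounded):
                raise ValueError("label map contains non-integer values")
            self.label_map = rounded.astype(np.int64)
        bad_lobes = set(self.lobe_lookup.values()) - set(LOBES) - {"ignore"}
        if bad_lobes:
            raise ValueError(f"unknown lobe name(s) in lookup: {sorted(bad_lobes)}")
        self.ignored = frozenset(
            k for k, v in self.lobe_lookup.items() if v == "ignore"
        )
        present = set(np.unique(self.label_map).tolist()) - {0}
        unlisted = present - set(self.lobe_lookup)
        if unlisted:
            if not self.allow_unlisted:
                raise ValueError(
                    f"label(s) {sorted(unlisted)[:10]} present in the map but "
                    "absent from the lobe lookup; add them (possibly as "
                    "'ignore') or pass allow_unlisted=True"
                )
            warnings.warn(
                f"ignoring {len(unlisted)} unlisted label(s)", stacklevel=2
            )

    def lobe_mask(self, lobe: str) -> np.ndarray:
        if lobe not in LOBES:
            raise ValueError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
        labels = [k for k, v in self.lobe_lookup.items() if v == lobe]
        return np.isin(self.label_map, labels)

    @classmethod
    def from_tsv(
        cls,
        label_map: np.ndarray,
        tsv_path: str | Path | None = None,
        affine: np.ndarray | None = None,
        allow_unlisted: bool = False,
    ) -> "LobeParcellation":
        """Build from a TSV with columns ``label_id``, ``parcel_name``, ``lobe``.

        With ``tsv_path=None`` the shipped Desikan-Killiany default is used
        (FreeSurfer ctx-lh-*/ctx-rh-* label ids 1000+/2000+).
        """
        if tsv_path is None:
            ref = resources.files("ifw.data") / "dk_lobes.tsv"
            text = ref.read_text()
        else:
            text = Path(tsv_path).read_text()
        lookup: dict[int, str] = {}
        reader = csv.DictReader(text.splitlines(), delimiter="\t")
        for row in reader:
            lookup[int(row["label_id"])] = row["lobe"]
        return cls(
            label_map=label_map,
            lobe_lookup=lookup,
            affine=affine,
            allow_unlisted=allow_unlisted,
        )


def roi_mean(
    map_: ScalarMap | np.ndarray, parcellation: LobeParcellation, lobe: str
) -> tuple[float, int]:
    """Arithmetic mean of the map over one lobe.

    Missing-coded (NaN) map voxels are excluded from both the numerator
    and the voxel count.  An empty lobe yields (nan, 0) with a warning.
    """
    if isinstance(map_, ScalarMap):
        values = map_.values
        if parcellation.affine is not None:
            check_geometry(
                values.shape,
                map_.affine,
                parcellation.label_map.shape,
                parcellation.affine,
            )
    else:
        values = np.asarray(map_, dtype=float)
    if values.shape != parcellation.label_map.shape:
        raise ValueError(
            f"map shape {values.shape} does not match label map "
            f"{parcellation.label_map.shape}"
        )
    in_lobe = parcellation.lobe_mask(lobe)
    vals = values[in_lobe]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn(f"lobe {lobe} has no valid voxels", stacklevel=2)
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def summarize_subject(
    map_: ScalarMap | np.ndarray,
    parcellation: LobeParcellation,
    subject_id: str,
    timepoint: float,
    measure_name: str = "ifw",
) -> pd.DataFrame:
    """Per-lobe means for one subject/timepoint as a tidy long table.

    Always returns eight rows (one per lobe); lobes without valid voxels
    carry NaN values and n_voxels = 0, never a silent zero fill.
    """
    rows = []
    for lobe in LOBES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value, n = roi_mean(map_, parcellation, lobe)
        rows.append(
            {
                "subject_id": subject_id,
                "timepoint_years": float(timepoint),
                "roi": lobe,
                "measure_name": measure_name,
                "value": value,
                "n_voxels": n,
            }
        )
    missing = [r["roi"] for r in rows if r["n_voxels"] == 0]
    if missing:
        warnings.warn(
            f"subject {subject_id}: no valid voxels in {missing}", stacklevel=2
        )
    return pd.DataFrame(rows)
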
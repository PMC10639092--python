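"""Brain parcellation used as the node set of every network.

The default parcellation has 82 regions, 41 per hemisphere (cerebellum
excluded): 34 cortical regions per hemisphere in the Desikan-Killiany
naming convention plus 7 subcortical grey-matter structures per
hemisphere from a standard automated segmentation.  Node labels are
``lh_<name>`` / ``rh_<name>``; left-hemisphere nodes come first, in a
fixed name order, so node ids are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import DataAlignmentError

CORTICAL_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudal_anterior_cingulate",
    "caudal_middle_frontal",
    "cuneus",
    "entorhinal",
    "frontal_pole",
    "fusiform",
    "inferior_parietal",
    "inferior_temporal",
    "insula",
    "isthmus_cingulate",
    "lateral_occipital",
    "lateral_orbitofrontal",
    "lingual",
    "medial_orbitofrontal",
    "middle_temporal",
    "paracentral",
    "parahippocampal",
    "pars_opercularis",
    "pars_orbitalis",
    "pars_triangularis",
    "pericalcarine",
    "postcentral",
    "posterior_cingulate",
    "precentral",
    "precuneus",
    "rostral_anterior_cingulate",
    "rostral_middle_frontal",
    "superior_frontal",
    "superior_parietal",
    "superior_temporal",
    "supramarginal",
    "temporal_pole",
    "transverse_temporal",
)

SUBCORTICAL_REGIONS: tuple[str, ...] = (
    "accumbens_area",
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus_proper",
)

#: Default-mode-network hub regions attenuated in the synthetic PSE group.
#: These are the regions that show group differences in the regional
#: analysis (cingulate/precuneus/parietal hubs plus insula).
DEFAULT_HUB_REGIONS: tuple[str, ...] = (
    "precuneus",
    "posterior_cingulate",
    "caudal_anterior_cingulate",
    "insula",
    "superior_frontal",
    "supramarginal",
    "inferior_parietal",
)

#: Default community assignment (by region name, mirrored bilaterally)
#: used to build the block-modular ground-truth covariance.
DEFAULT_MODULES: dict[str, int] = {}
for _r in DEFAULT_HUB_REGIONS + ("isthmus_cingulate", "rostral_anterior_cingulate",
                                 "medial_orbitofrontal"):
    DEFAULT_MODULES[_r] = 0  # default-mode / hub module
for _r in ("precentral", "postcentral", "paracentral", "superior_parietal",
           "superior_temporal", "transverse_temporal"):
    DEFAULT_MODULES[_r] = 1  # sensorimotor
for _r in ("cuneus", "pericalcarine", "lateral_occipital", "lingual", "fusiform"):
    DEFAULT_MODULES[_r] = 2  # visual
for _r in SUBCORTICAL_REGIONS:
    DEFAULT_MODULES[_r] = 4  # subcortical
for _r in CORTICAL_REGIONS:
    DEFAULT_MODULES.setdefault(_r, 3)  # remaining association cortex
del _r

HEMISPHERES = ("left", "right")
_HEMI_PREFIX = {"left": "lh", "right": "rh"}


@dataclass(frozen=True)
class Parcellation:
    """An ordered node table: node_id, name, hemisphere, tissue_class."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"node_id", "name", "hemisphere", "tissue_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataAlignmentError(f"parcellation table missing columns {sorted(missing)}")
        ids = self.table["node_id"].to_numpy()
        if len(set(ids)) != len(ids) or list(ids) != list(range(len(ids))):
            raise DataAlignmentError("node_ids must be unique and contiguous from 0")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        """Unique per-node labels ``lh_<name>`` / ``rh_<name>``."""
        return [
            f"{_HEMI_PREFIX[h]}_{n}"
            for h, n in zip(self.table["hemisphere"], self.table["name"])
        ]

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    @property
    def hemispheres(self) -> list[str]:
        return list(self.table["hemisphere"])

    def hemisphere_nodes(self, hemisphere: str) -> list[int]:
        """Node ids of one hemisphere."""
        if hemisphere not in HEMISPHERES:
            raise DataAlignmentError(f"unknown hemisphere {hemisphere!r}")
        mask = self.table["hemisphere"] == hemisphere
        return list(self.table.loc[mask, "node_id"])

    def nodes_named(self, name: str) -> list[int]:
        """Node ids (one per hemisphere) for a region name."""
        mask = self.table["name"] == name
        ids = list(self.table.loc[mask, "node_id"])
        if not ids:
            raise DataAlignmentError(f"no region named {name!r}")
        return ids

    def node_id(self, name: str, hemisphere: str) -> int:
        mask = (self.table["name"] == name) & (self.table["hemisphere"] == hemisphere)
        ids = list(self.table.loc[mask, "node_id"])
        if len(ids) != 1:
            raise DataAlignmentError(f"no unique node {name!r}/{hemisphere!r}")
        return ids[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Parcellation":
        return cls(pd.read_csv(path))


def make_default_parcellation() -> Parcellation:
    """Build the default 82-node parcellation (41 per hemisphere).

    Left-hemisphere nodes occupy ids 0..40 and right-hemisphere nodes
    41..81, each hemisphere ordered cortical-then-subcortical by name,
    so every left node has a homologous right node with the same name.
    """
    rows = []
    for hemi in HEMISPHERES:
        for name in CORTICAL_REGIONS:
            rows.append((name, hemi, "cortical"))
        for name in SUBCORTICAL_REGIONS:
            rows.append((name, hemi, "subcortical"))
    table = pd.DataFrame(rows, columns=["name", "hemisphere", "tissue_class"])
    table.insert(0, "node_id", range(len(table)))
    return Parcellation(table)
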
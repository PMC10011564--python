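"""Assembly of the 224-feature somatic profile for one sample.

Profile order: 96 SBS channels, 83 indel channels, 45 copy-number
features (six categories) — all named, in a stable canonical order.
"""

from __future__ import annotations

import pandas as pd

from .copynumber_features import DEFAULT_SCHEMA, CnFeatureSchema, extract_cn_features
from .mutation_features import ID83_CHANNELS, SBS96_CHANNELS, MutationCatalog
from .types import ArmMap, CopySegment


def feature_names(schema: CnFeatureSchema = DEFAULT_SCHEMA) -> list[str]:
    """The canonical 224 feature names in profile order."""
    return list(SBS96_CHANNELS) + list(ID83_CHANNELS) + schema.feature_names


def build_profile(
    catalog: MutationCatalog,
    segments: list[CopySegment],
    arm_map: ArmMap,
    schema: CnFeatureSchema = DEFAULT_SCHEMA,
) -> pd.Series:
    """Concatenate mutation catalog counts and copy-number features."""
    cn = extract_cn_features(segments, arm_map, schema)
    profile = pd.concat(
        [catalog.sbs_series().astype(float), catalog.indel_series().astype(float), cn]
    )
    profile.name = catalog.sample_id
    return profile
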
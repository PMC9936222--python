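"""Canonical radiomic feature manifest.

The extractor emits exactly the identifiers listed in the versioned
manifest file, in file order. Identifiers follow the IBSI dotted
nomenclature (``stat.skew``, ``ih.cov``, ``szm.lze``, ...), grouped into
eleven families: intensity statistics (stat), intensity histogram (ih),
intensity-volume histogram (ivh), local intensity (loc), morphology
(morph), grey-level co-occurrence (cm), run length (rlm), size zone
(szm), distance zone (dzm), neighbourhood grey tone difference (ngt)
and neighbouring grey level dependence (ngl).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

MANIFEST_VERSION = "v1"
N_FEATURES = 154


@lru_cache(maxsize=None)
def feature_manifest(version: str = MANIFEST_VERSION) -> tuple[str, ...]:
    """Return the ordered tuple of feature identifiers for a manifest version."""
    ref = resources.files("petrad.data").joinpath(f"manifest_{version}.txt")
    names = [
        line.strip()
        for line in ref.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate identifiers in manifest {version}")
    return tuple(names)


def manifest_index(version: str = MANIFEST_VERSION) -> dict[str, int]:
    """Identifier -> position map, used for deterministic tie-breaking."""
    return {name: i for i, name in enumerate(feature_manifest(version))}
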
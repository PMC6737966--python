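import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitomorph import (
    Compartment,
    LabelTable,
    LabelVolume,
    SemanticClass,
    VoxelSpacing,
    assign_all,
    connected_components,
    generate_cohort,
    load_preset,
    measure_all,
)

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


def make_volume(grid, spacing=(8.0, 8.0, 8.0), pairs=None, source_id="test"):
    """Build a LabelVolume from an integer grid; pairs maps label -> class."""
    grid = np.asarray(grid)
    if pairs is None:
        pairs = {int(l): SemanticClass.MITOCHONDRION for l in np.unique(grid) if l != 0}
    return LabelVolume(
        grid=grid.astype(np.uint16),
        spacing=VoxelSpacing(*spacing),
        labels=LabelTable.from_pairs(pairs),
        source_id=source_id,
    )


def measure_preset(name, seed=None):
    """Run the full pipeline on a region preset; returns per-compartment
    volume lists plus the params and manifest (shared across acceptance
    tests through the session-scoped fixture below)."""
    params = load_preset(name, seed=seed)
    volume, manifest = generate_cohort(params)
    records = measure_all(volume)
    objects = connected_components(volume, SemanticClass.MITOCHONDRION)
    assign_all(objects, volume, records=records)
    pre = [r.volume_um3 for r in records if r.compartment == Compartment.PRESYNAPTIC]
    post = [r.volume_um3 for r in records if r.compartment == Compartment.POSTSYNAPTIC]
    return {
        "params": params,
        "manifest": manifest,
        "records": records,
        "pre_volumes": pre,
        "post_volumes": post,
    }


@pytest.fixture(scope="session")
def preset_run():
    """Lazily computed, cached full-pipeline runs of the region presets."""
    cache = {}

    def run(name):
        if name not in cache:
            cache[name] = measure_preset(name)
        return cache[name]

    return run
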
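"""Enumerate every stimulus configuration of the sensitivity protocol.

Seed configurations add one stimulus per IAR (totals 1-4); dense levels
layer regional stimuli around the seeds (totals up to 384); sparse variants
keep only each level's peripheral extremes (e.g. 28 dense -> 12 sparse,
384 dense -> 36 sparse); RBBB/LBBB remove one ventricle's stimuli from the
12-stimulus sparse configuration.
"""

from hearts import GeometryParams, build_ventricles, define_iars
from hearts.stimuli import (SPARSE_NAMES, SWEEP_NAMES, bbb_configuration,
                            configuration_by_name)

geom = build_ventricles(GeometryParams(spacing_mm=2.5))
iars = define_iars(geom)

print("name        total   per-IAR counts")
for name in list(SWEEP_NAMES) + list(SPARSE_NAMES):
    cfg = configuration_by_name(name, iars)
    print(f"{cfg.name:10s} {cfg.total:6d}   {cfg.counts_by_tag()}")

for side in ("right", "left"):
    cfg = bbb_configuration(side, iars)
    print(f"{cfg.name:10s} {cfg.total:6d}   {cfg.counts_by_tag()}")
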
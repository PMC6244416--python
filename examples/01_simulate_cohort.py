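"""Simulate a methylation study cohort with a planted episignature.

Builds the default synthetic study — 28 cases in four subtypes (14/5/2/7)
against a 400-sample control pool — with a shared planted probe signature,
subtype-specific blocks and three planted multi-probe regions, then writes
it to disk as plain-text files.
"""

import tempfile
from pathlib import Path

import episig as es

study = es.simulate_study(seed=7)
cohort, truth = study.cohort, study.truth

print(f"cohort: {cohort.n_probes} probes x {cohort.n_samples} samples")
print(cohort.samples["group"].value_counts().to_string())
for label, probes in truth.planted_probe_ids.items():
    print(f"planted block {label!r}: {len(probes)} probes")
print(f"planted regions: {[(c, s, e) for c, s, e, _ in truth.planted_regions]}")

out = Path(tempfile.mkdtemp(prefix="episig_"))
paths = es.export_fixture(cohort, truth, out)
print(f"wrote {sorted(p.name for p in paths.values())} to {out}")

# Every downstream example rebuilds this cohort from the same seed, so the
# block sizes above are the ground truth the other scripts try to recover.
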
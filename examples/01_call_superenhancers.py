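"""Call super-enhancers for one synthetic sample.

Generates a small cohort bundle, then stitches one sample's H3K27ac peaks,
ranks stitched regions by signal mass and splits them at the hockey-stick
inflection.  The printed cutoff is the signal of the last region on the flat
part of the ranked curve; everything above it is a super-enhancer.
"""

import tempfile
from pathlib import Path

from sescout import (
    GeneratorConfig,
    SignalTrack,
    call_sample_ses,
    generate_cohorts,
    read_bed,
    read_gene_table,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle, truth = generate_cohorts(GeneratorConfig(seed=1), Path(tmp) / "bundle")
    sample = bundle.samples["COREAD"][0]
    tss = [g.tss for g in read_gene_table(bundle.genes)]

    calls = call_sample_ses(
        read_bed(sample.peaks),
        SignalTrack.from_bedgraph(sample.signal),
        tss=tss,
        sample_id=sample.sample_id,
    )

    hk = calls.hockey
    print(f"sample {sample.sample_id}: {len(hk.regions)} stitched regions")
    print(f"hockey-stick cutoff signal: {hk.cutoff_signal:.1f}")
    print(f"{len(calls.superenhancers)} super-enhancers:")
    for r in calls.superenhancers:
        print(f"  {r.span}  signal={r.signal:.0f}  peaks={r.n_constituents}")
    planted = {str(s.span) for s in truth.ses_for_cohort("COREAD")}
    print(f"planted SEs in this cohort: {sorted(planted)}")
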
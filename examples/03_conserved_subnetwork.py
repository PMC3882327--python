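"""Find the cross-stage conserved epigenetic subnetwork.

Runs the full pipeline on a default-size synthetic cohort and prints
the conserved gene set found by propagating the top size-4
subnetworks of each stage, next to the planted truth.
"""

import tempfile

from epistage import RunConfig, SimulationConfig, run_pipeline, simulate_bundle

with tempfile.TemporaryDirectory() as tmp:
    paths, truth = simulate_bundle(SimulationConfig(seed=1), tmp + "/bundle")
    result = run_pipeline(RunConfig.for_bundle(paths, tmp + "/out", seed=1))

    print(result.summary.to_string(index=False))

    print("\ntop-ranked size-4 subnetwork per stage "
          "(score = (sum node strengths + sum edge strengths) / k):")
    for stage, subs in result.subnetworks.items():
        top = subs[0]
        print(f"  stage {stage}: {','.join(top.genes)}  strength={top.strength:.3f}")

    print(f"\nconserved gene set across stages: {sorted(result.conserved)}")
    print(f"planted conserved core:            {sorted(truth.core_genes)}")
# The conserved set is the intersection of the best extended
# subnetwork of each stage; on this benchmark it recovers the
# planted 7-gene core exactly.
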
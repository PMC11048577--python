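"""Run the whole analysis end to end and inspect the composite accuracy.

generate -> screen -> ROC -> score -> evaluate, with every stage artifact
(cohort CSV, screening table, per-marker ROC summaries, per-patient scores,
accuracy table, reproducibility manifest) written to a temporary directory.
"""

import json
import tempfile
from pathlib import Path

import idhscore as ih

with tempfile.TemporaryDirectory() as tmp:
    paths = ih.run_pipeline(ih.RunConfig(seed=11, out_dir=Path(tmp) / "run"))
    print("artifacts written:")
    for name, path in sorted(paths.items()):
        print(f"  {name:<9} {path.name}")

    accuracy = json.loads(paths["accuracy"].read_text())
    print(
        f"\nfull9 card on this synthetic cohort: "
        f"{accuracy['correct_n']}/{accuracy['decided_n']} decided cases correct "
        f"({accuracy['accuracy_decided']:.1%}); overall {accuracy['accuracy_overall']:.1%}"
    )
    print(
        "\nSynthetic cohorts use independent features, so this accuracy reflects "
        "the generative model rather than the real patients' joint distribution; "
        "it varies seed to seed at n=82 but stays well above chance."
    )
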
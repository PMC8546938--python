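"""Sample-size planning for the prevalence survey.

A cross-sectional prevalence design with hypothesised prevalence 50%,
90% two-sided confidence, 5% absolute precision and no design effect
needs 271 children per centre; five centres give a planned total of 1355.
"""

import json
from pathlib import Path

from screenseven.design import SampleSizeSpec, required_sample_size

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    spec = SampleSizeSpec(
        hypothesized_prevalence=0.5,
        confidence_level=0.90,
        absolute_precision=0.05,
        design_effect=1.0,
    )
    per_centre = required_sample_size(spec)
    out = {
        "per_centre": per_centre,
        "n_centres": 5,
        "planned_total": 5 * per_centre,
        "spec": spec.__dict__,
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "sample_size.json").write_text(json.dumps(out, indent=2))
    print(f"required per centre: {per_centre} (5 centres -> {5 * per_centre})")


if __name__ == "__main__":
    main()
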
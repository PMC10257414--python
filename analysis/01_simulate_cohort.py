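"""Generate the synthetic TNBC cohort and summarize its composition.

Writes the per-patient FCS files and ground truth to scratch/cohort (binary,
not part of the deliverable) and the clinical table plus compartment tallies
to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, SEED, get_cohort  # noqa: E402

from cytomet.simulate import CohortConfig, generate_cohort  # noqa: E402


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = generate_cohort(CohortConfig(seed=SEED), out_dir=SCRATCH / "cohort")

    n_cells = cohort.truth.groupby("patient_id").size()
    print(f"cohort: {len(cohort.events)} patients, "
          f"{n_cells.sum()} cells ({n_cells.min()}-{n_cells.max()} per patient)")
    comp = cohort.truth["compartment"].value_counts()
    print("compartment tally:")
    print(comp.to_string())

    cohort.clinical.to_csv(RESULTS / "clinical.csv", index=False)
    comp.rename("n").to_csv(RESULTS / "compartment_tally.csv")
    print(f"\nFCS + ground truth under {SCRATCH / 'cohort'}; "
          f"tables under {RESULTS}")


if __name__ == "__main__":
    main()
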
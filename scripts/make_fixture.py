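"""Regenerate the frozen 12-gene worked fixture shipped with the package.

Run from the repository root:  python scripts/make_fixture.py
Rewrites src/genesieve/fixtures/ deterministically from the frozen spec.
"""

import warnings
from pathlib import Path

from genesieve.features import write_matrix
from genesieve.pipeline import featurize, run_synthetic_screen
from genesieve.sequence_io import write_gene_set, write_manifest
from genesieve.synthetic import WORKED_FIXTURE_SPEC, generate, worked_fixture_dir


def main() -> None:
    warnings.filterwarnings("ignore")
    out = worked_fixture_dir()
    out.mkdir(parents=True, exist_ok=True)
    records, truth = generate(WORKED_FIXTURE_SPEC)
    write_gene_set(records, out / "cds.fasta", out / "protein.fasta", out / "pairing.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t")
    write_manifest(records, out / "manifest.json", seed=WORKED_FIXTURE_SPEC.seed)

    matrix = featurize(records)
    write_matrix(matrix, out / "features.tsv")

    result, _ = run_synthetic_screen(WORKED_FIXTURE_SPEC, n_cycles=3, max_iter=400)
    trace = result.heldout_trace.samples[
        [c for c in result.heldout_trace.samples.columns if c.startswith(("votes_", "survived_"))]
    ].copy()
    trace["total_votes"] = result.heldout_trace.samples["total_votes"]
    trace.to_csv(out / "trace.tsv", sep="\t")
    (out / "survivor_counts.txt").write_text(" ".join(map(str, result.survivor_counts)) + "\n")
    print("fixture written to", out)


if __name__ == "__main__":
    main()
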
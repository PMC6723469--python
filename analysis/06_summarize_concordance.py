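"""Final accounting: concordance totals, per-enzyme/per-species copy-number
matrix with discrepancy flags, and CDS length statistics per category."""

from common import RESULTS, parse_seed, pipeline_config

from annoconcord.pipeline import run_subcommand
from annoconcord.summary import plot_copy_numbers


def main() -> None:
    config = pipeline_config(parse_seed(__doc__))
    report, matrix, lengths = run_subcommand("report", config)
    print("final concordance accounting (after rescue):")
    for key, value in report.to_series().items():
        print(f"  {key:14s} {value:4d}")
    discrepant = matrix[matrix["discrepant"]]
    zero = matrix[matrix["any_zero"]]
    print(f"copy-number cells: {len(matrix)}, discrepant: {len(discrepant)}, with zeros: {len(zero)}")
    print("\nlength statistics (nt) by enzyme/source/category:")
    print(lengths.to_string(float_format=lambda v: f"{v:.0f}"))
    fig_path = RESULTS / "report" / "copy_number_matrix.svg"
    plot_copy_numbers(matrix, fig_path)
    print(f"\nfigure written to {fig_path}")


if __name__ == "__main__":
    main()
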
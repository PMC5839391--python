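#!/usr/bin/env python
"""Generate the synthetic study bundle: toy metabolic model, MaxQuant-style
proteomics with a planted -1.0 log2 module effect, GMT annotation and
median-effect viability tables.  Everything downstream reads from
results/inputs/."""

from pathlib import Path

from fluxnode.pipeline import PipelineConfig, _simulate_inputs

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_yaml(Path(__file__).resolve().parents[1] / "configs" / "demo.yaml")
    model, x, annotation, viability = _simulate_inputs(cfg, OUT)
    print(f"model: {len(model.reactions)} reactions, {len(model.metabolites)} metabolites")
    print(f"proteomics: {x.intensities.shape[0]} proteins x {x.intensities.shape[1]} columns")
    print(f"annotation: {len(annotation)} terms; viability: {len(viability.data)} lines")
    print(f"wrote bundle to {OUT}")


if __name__ == "__main__":
    main()
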
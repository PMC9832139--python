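"""End-to-end demo: generate, split, augment, train both stages, evaluate.

A deliberately small run (24 crops of 64x64, 300 + 300 SGD iterations) so
it finishes in a couple of minutes on one CPU; report.csv, indices.csv, a
checkpoint and a JSON-lines run log land in examples/output/demo_run.

The printed report contains the five segmentation metrics (CPA/MPA for
pixel recall, IoU/MIoU/FWIoU for overlap) and the three decision metrics
(SE/SP/ACC), all in percent.  With this little training the decision
metrics are usually already high while pixel IoU stays modest — the
segmentation needs more iterations than the classifier.
"""

from tonguecrack import run_pipeline

metrics = run_pipeline(
    {
        "synth": {"n_pos": 12, "n_neg": 12, "image_size": 64, "contrast_gap": 60},
        "train": {"epochs_seg": 300, "epochs_dec": 300},
    },
    out_dir="examples/output/demo_run",
)

for name, value in metrics.items():
    print(f"{name:10s} {100 * value:5.1f}%")
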
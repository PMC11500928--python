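# blindcut

Blinded, randomized scoring of video and image regions — a headless
library and CLI for removing observer bias from manual media analysis.

## Why

Manual scoring of videos and images (seizure staging of zebrafish in a
multi-well plate, cell phenotypes under drug treatment, camera-trap
classification) is biased when the scorer knows which condition each
recording belongs to — and the person who ran the experiment always
knows. `blindcut` lets a single researcher score their own data
blinded:

1. **Segment** — cut each source video/image into labeled rectangular
   regions (e.g. one plate well per segment, labeled `A1` … `E12`).
2. **Randomize** — pool the segments from all sources and shuffle them
   once with an explicit Fisher–Yates pass: for `i = n−1 … 1`, swap
   position `i` with a uniform draw from `{0 … i}`, giving every one of
   the `n!` orders probability `1/n!`.
3. **Review** — segments appear in shuffled order under anonymous IDs
   (`S001`, `S002`, … = presentation rank, nothing else); the scorer
   enters free-text notes for each user-named stage. Sessions persist
   after every score and resume without ever re-shuffling.
4. **Export** — scores are joined back through the blinded IDs to their
   labels and source files, written as `results.csv` and
   `results.xlsx` (one row per segment: label, source file, one column
   per stage).

Blinded segment files are re-encoded from raw pixels with no container
metadata, and no filename, ID or review output contains any label or
source-name substring. Pixel resolution is never resampled; crops are
exact subarrays. A synthetic multi-well-plate generator with full
ground truth (well grid, per-well condition, exact blob trajectories)
makes the whole pipeline testable end to end without any real
recordings.

Supported formats: `.mp4`, `.avi` video; `.png`, `.jpg`/`.jpeg`,
`.bmp` images. AVI is written losslessly (uncompressed frames); MP4 is
Motion-JPEG (dimensions and frame count guaranteed, pixel values
lossy).

## Worked example

Generate a synthetic 2×3-well plate video in which wells differ in
motion amplitude (columns at 0, 2 and 6 px/frame), then run the full
blinded workflow:

```sh
blindcut synth --rows 2 --cols 3 --frames 120 --levels 0,2,6 --seed 42 --out synthdata
# wrote synthdata/plate.avi (160x112, 120 frames) and groundtruth.json (6 wells)

python -c "import json; t=json.load(open('synthdata/groundtruth.json')); \
           json.dump(t['segmentation'], open('segmentation.json','w'))"

blindcut segment --config segmentation.json --stages "stage I,stage II" \
                 --out results --seed 7
# session created: 6 segments from 1 source file(s); blinded media in results/blind
```

`results/blind/` now holds `S001.avi` … `S006.avi` in shuffled order.
Score them — interactively (`blindcut review results` prompts per
stage, showing only the blinded media path) or in batch from a CSV of
`blinded_id,stage I,stage II` rows in presentation order. Here each
segment was scored with the built-in motion scorer
(`blindcut.synthetic.activity_score`, mean absolute pixel change per
frame):

```sh
blindcut review results --scores scores.csv
# scored 6 segment(s); 0 remaining
# session complete
blindcut export results
# wrote results/results.csv and results/results.xlsx (6 rows)
cat results/results.csv
```

```
label,source_file,stage I,stage II
A1,plate.avi,0.000,ok
A2,plate.avi,4.710,ok
A3,plate.avi,11.945,ok
B1,plate.avi,0.000,ok
B2,plate.avi,4.705,ok
B3,plate.avi,12.482,ok
```

After unblinding, the scores recover the planted conditions exactly:
the stationary wells (`A1`, `B1`, activity 0) score 0.000, the 2
px/frame wells score ≈ 4.7, the 6 px/frame wells ≈ 12 — group means
strictly ordered by the true activity level, even though the scorer
only ever saw anonymous segments in shuffled order.

Configs can also list explicit rectangles per source
(`{"source": ..., "segments": [{"label": "A1", "x": 0, "y": 0, "w": 40,
"h": 40}]}`) or use the plate-grid shorthand (`rows`, `cols`,
`origin`, `pitch`, `well_size`). Multiple sources of the same media
type are pooled into one randomization.

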
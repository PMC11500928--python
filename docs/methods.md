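# Methods

## The problem

When humans score video or image data — seizure staging in zebrafish,
cell morphology under drug treatment, wildlife camera traps — knowing
which experimental condition a recording belongs to biases the score.
The standard remedy, handing the data to a naive scorer, costs personnel
and only dilutes the bias. `blindcut` removes the information instead:
it cuts each source recording into labeled rectangular segments (one
well of a plate, one field of view), shuffles the pooled segments, and
presents them for scoring under anonymous IDs. Only after every segment
is scored are the scores joined back to their labels and source files.
A single researcher can therefore run and score their own experiment
blinded.

## Randomization

The shuffle is the explicit backward Fisher–Yates pass: for
`i = n−1 … 1`, draw `j` uniformly from `{0, …, i}` and swap positions
`i` and `j`. Every one of the `n!` orders has probability `1/n!`. The
permutation is drawn exactly once, only after *all* sources have been
segmented (so the pool is complete), and is persisted; pausing and
resuming never re-randomizes. Draws come from Python's Mersenne-Twister
`random.Random`; the seed — user-supplied or drawn once from OS entropy
— is recorded in the session state for audit. Seedability exists for
reproducibility and testing and is never surfaced during review.

Uniformity is verified empirically in the test suite: 24 000
independently seeded shuffles of 4 items, chi-square over the 24
permutation counts (23 df), requiring `p > 0.001` — a deliberately
permissive threshold whose purpose is to catch implementation bias
(a classic wrong variant, swapping with `j ∈ {0…n−1}`, fails it
decisively), not to certify the generator.

## Blinding model

Blinded IDs are `S001`, `S002`, … assigned in *shuffled* order, so an ID
encodes its presentation rank and nothing else. The numeric part always
keeps at least one leading zero (pad width `max(3, digits(n)+1)`);
since labels (`A1`–`Z36`) never contain leading zeros, no label can
occur as a substring of any ID, for any session size. Segment media are
re-encoded from raw pixels and written as `<ID>.<ext>` with no container
metadata, so neither filename nor file content can carry provenance.
The label↔ID key lives only in `session.json`, which the review
commands never print; `scan_for_leaks` is used at session creation and
throughout the tests to assert that nothing shown during review
contains a label or a source-file name/stem.

## Session persistence

All state — segments, permutation, IDs, scores, cursor, seed — is one
JSON document with a schema version. Every recorded score rewrites it
atomically (write temp file, `os.replace`), so a crash between scores
loses nothing. Loading validates the permutation, ID distinctness,
cursor/score consistency and stage coverage; a file that fails any
check is refused outright rather than repaired, because any repair
path risks silently regenerating the order. Draft notes for a segment
whose dialog was abandoned are not kept: notes commit atomically per
segment or not at all.

## Media handling

Supported formats are `.mp4`/`.avi` video and `.png`/`.jpg`/`.jpeg`/
`.bmp` images. Images go through Pillow. Video goes through two small
purpose-built container codecs:

* **AVI** holds uncompressed 24-bit BI_RGB frames — lossless, so a
  written segment read back is bit-identical to the cropped pixels, and
  decodable by essentially every player. MJPEG-in-AVI files from other
  tools are also readable.
* **MP4** holds Motion-JPEG samples (Pillow JPEG, quality 95) in a
  minimal ISO-BMFF box tree; it is lossy, and its contract is
  dimensions and frame count, not pixel values. MP4 files using other
  codecs (H.264 …) are rejected with a decode error rather than
  misread.

Cropping is pure array slicing on the decoded frames — 0-based,
half-open rectangles that must lie fully inside the frame (no clamping:
a silently clamped rectangle would change segment content invisibly).
No resampling ever occurs anywhere, so output resolution always equals
the crop size exactly. Segments are re-encoded, never stream-copied:
re-encoding is what guarantees a metadata-free blinded file.

## Label grammar

`^[A-Z]([1-9]|[12][0-9]|3[0-6])$` — one uppercase letter then 1–36, no
leading zeros: the addressing scheme printed on multi-well plates.
Duplicates are rejected across the *whole* analysis (all batched
sources pooled), since segments from every file mix before the shuffle.
A label is permanent once assigned. Number-only and letter-only labels
are excluded by the grammar.

## Synthetic plate fixtures

`blindcut.synthetic` renders the kind of recording the workflow is
designed for: a dark plate with a grid of square wells, one bright disk
("blob", radius `well_size/8`) per well, moving as a bounded random
walk. Each step has length equal to the well's *activity level*
(px/frame, the condition variable) in a uniformly random direction,
reflecting off the well walls; the disk never leaves its well, and
activity 0 is a perfectly stationary blob. Each well draws from its own
seeded RNG stream, so plates are bit-reproducible and adding wells
never perturbs existing ones. The generator returns full ground truth:
the well grid (directly usable as a segmentation config), each well's
activity and the exact per-frame blob-center trajectory.

Defaults mirror a 96-well behavioral assay in which rows A–E are
occupied (60 wells) and treatment strength varies across four 3-column
bands, strongest in columns 1–3 and untreated in columns 10–12, with
activity levels 8/4/2/0.5 px/frame, 200 frames at 25 fps. The
untreated default is 0.5 rather than 0 because control animals still
move.

What the fixtures do *not* model: real animal kinematics (burst swims,
turns, seizure-stage morphology), illumination gradients, sensor noise,
compression artifacts of real camera files, or between-animal
variability. Passing the end-to-end test therefore shows that the
*pipeline* preserves and correctly reassembles condition information —
not that any particular behavioral endpoint is scorable.

`activity_score` — the deterministic stand-in for a human scorer — is
the mean over consecutive frame pairs of the mean absolute per-pixel
intensity difference. It is zero iff all frames are identical and
increases with the fraction of the image that changes per frame, which
makes it monotone in blob step size at fixed geometry.

## Numerical and policy choices

* Frame pixel type is `uint8` throughout; `activity_score` accumulates
  in int64/float64 to avoid wrap-around.
* Segment videos inherit the source fps; a source with no usable rate
  defaults to 25 fps.
* Results rows sort by source file, then label in natural well order
  (letter, then numeric value: `A2` before `A10`).
* `results.csv` (UTF-8, RFC-4180 quoting) is the canonical output;
  `results.xlsx` is written alongside with identical cell content.
* Partial exports mark unscored stage cells `(pending)`.
* Zero segments or zero stages reject session creation; an empty
  session has no meaningful randomization to protect.
* Overlapping rectangles are allowed (regions of interest may
  legitimately overlap); out-of-frame rectangles are not.

## Verification sizes

The self-contained checks run at desk scale: shuffle uniformity at
n = 4 with 24 000 draws; crop exactness on 100 random rectangles per
media type; resume-equivalence and the output contract on 60-segment
sessions over a synthetic 60-well plate image; blinding scans on a
60-well, 3-frame plate video named after a treated condition; and
condition recovery on a 3×4-well plate (activity 0/2/6 px/frame, four
wells per level, 200 frames) through the complete
segment → blinded review → export pipeline, requiring the unblinded
group means to be strictly ordered by level (Spearman ρ of group means
vs level = 1) with the stationary group scoring exactly zero.

## Known limitations

* No interactive (mouse-drawn) region selection and no GUI; rectangles
  come from a config file or the plate-grid shorthand.
* Only rectangular regions.
* MP4 reading is limited to Motion-JPEG; real-world H.264 files must be
  converted or recorded as AVI/MJPEG first.
* Review playback is delegated to the user's media player; the CLI
  prints the blinded media path and collects text notes.
* No downstream statistics on the exported table.
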
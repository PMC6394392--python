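# Methods

This note documents the data model, the execution semantics and the
numerical/design choices behind `datumflow`, and what the test suite's
guarantees do and do not establish about real workloads.

## Content addressing and trees

Blobs are named by the SHA-256 hex digest of their raw bytes.  SHA-256 was
chosen because it is ubiquitous, fast enough for this scale, and makes
accidental collisions a non-concern; the address is a pure function of
content, which is what gives deduplication, restart-stable addresses, and
tamper-evidence.  The local backend stores one file per blob under a
two-level fan-out (`objects/<aa>/<bb>/<digest>`) with write-to-temp +
atomic rename; the backend interface is four methods
(`write`/`read`/`exists`/`list`), so an S3-compatible object store can be
substituted without touching the engine.  The store is append-only: nothing
ever garbage-collects unreferenced blobs, which keeps every historical
commit readable forever at the cost of disk.

A file tree maps absolute slash-paths to blob references.  Its hash is the
SHA-256 of the canonical serialization — entries sorted bytewise by path,
each rendered `path\0address\n` — so tree equality is content equality,
independent of insertion order, commit ids, or wall time.  Trees reject a
path that is simultaneously a file and a directory prefix of another file
(`/a` plus `/a/b`): such a tree cannot be materialized on a filesystem, and
excluding it also guarantees that glob match roots never nest.  Empty
directories are not representable; directories exist implicitly as path
prefixes, the usual object-store convention.

## Commits and repositories

A repository is a linear chain of immutable commits (no branches; a commit's
parent is the head at commit time).  Commit ids are `<repo>@<ordinal>` —
deterministic and readable; all content comparisons in the engine and the
tests go through tree hashes, never ids.  User commits apply a change map
(bytes to add/update, `None` to delete) to the parent tree; untouched paths
keep their parent's blob references, so a k-file change on an n-file tree
stores at most k new blobs.  Deletion markers are supported in user commits
as a convenience; removed paths stay readable at all earlier commits.

All metadata (repos, commits, pipeline spec versions, jobs) lives in a
single SQLite file in the workspace, which survives restarts; blob bytes
never enter the catalog.

## Datums and glob patterns

A pipeline's glob pattern partitions the input tree into datums.  The
dialect is deliberately minimal: `/` (whole repo, one datum), `/*` (one
datum per top-level entry), and patterns of literal components with `*`
wildcards (`/plates/*`).  `**`, `?` and character classes are rejected —
the two patterns that matter in practice are `/` and `/*`, and a small
dialect keeps the disjointness argument airtight: every root matched by one
pattern has the same component depth, so datum file sets are pairwise
disjoint and the union over `/*` is exactly the tree.  `/` on an empty tree
yields zero datums rather than one empty datum, so user code never runs on
no input.

A datum's identity is the SHA-256 over its sorted (root-relative path,
address) pairs.  It depends only on the datum's own file names and bytes —
not on the commit, the repo, or time — which is precisely the equivalence
that licenses skipping: equal datum id ⇒ a correct engine may reuse the
previous outputs.

## Execution semantics

Stage commands run as local subprocesses in throwaway sandboxes, not
containers: the preserved contract is the filesystem interface (inputs
mounted under `pfs/<mount>/`, side inputs mounted whole, outputs collected
from an initially empty `pfs/out/`, `PFS_ROOT` pointing at the `pfs`
directory) and the exit-code semantics (0 = success, anything else = datum
failure with captured stderr).  A declared container image is carried as
inert metadata so specs round-trip.  Datum files are materialized under
their full repository paths inside the mount, so a stage reading the whole
repository (`/`) and a stage reading one file (`/*`) see the same layout.

A job runs at most `parallelism` datums concurrently (thread pool over
subprocesses); results are merged in datum order, so output content is
independent of completion order.  Two datums writing the same output path
is a hard job failure — under parallel completion a silent overwrite would
be nondeterministic — and per-datum output namespacing is deliberately the
stage command's responsibility.

**Failure atomicity.** A job either produces one output commit containing
the merged outputs of every datum, or (any datum failed, or a collision)
produces no output commit at all.  Downstream stages are only triggered by
a successful upstream job, so a failure cleanly truncates its branch of
the cascade and every repo head remains at the last fully consistent state.

**Incrementality.** The reuse reference is the most recent *successful*
job of the same pipeline at the same spec version whose side-input trees
are byte-identical.  Any of the three changing (spec semantics, side data,
or no prior success) forces a full recompute.  Datums present in the
reference with an equal datum id are skipped and their outputs carried
forward; datums that vanished contribute nothing.  These rules are chosen
to make one invariant hold unconditionally, and it is the central
correctness oracle of the test suite: after *any* sequence of commits, the
head output tree hash equals that of a single from-scratch run on the
final input state.  Spec version changes are detected via the SHA-256 of
the spec's canonical JSON (sorted keys; the inert `image` field excluded,
since it cannot affect local execution).

**Triggering.** Only commits to a pipeline's partitioned input trigger
jobs; side-input commits take effect at the next primary trigger.  Jobs in
a cascade run synchronously in topological order, so there is no notion of
a commit arriving mid-job; `flush-commit` exists for interface parity and
reports the already-settled downstream jobs.

## Provenance

Provenance is recorded eagerly: every job-origin commit stores its input
commit ids and spec version at creation, so lineage is a walk over stored
records, not a log reconstruction.  The lineage graph has commits and spec
versions as nodes, with edges from each output commit to its inputs and its
spec; leaves are user commits.  Skipped-datum reuse is invisible to
lineage on purpose — because incremental ≡ from-scratch, the reuse path
cannot change what was computed, only how fast.  The replay-sufficiency
test closes the loop: materializing the leaf commits and re-running the
referenced specs reproduces the output tree hash exactly.

## Scaling metrics and the scheduler simulator

Speedup S(N) = T₁/T_N and scaling efficiency S(N)/N.  Durations carry units
at the interface (`30.8h`, `37.3min`, `90s`) and are converted to minutes
internally, because benchmark tables mix hours for serial and minutes for
parallel runs.  Printed integers and percentages use round-half-up
(`78.75% → 79%`), the convention of such tables; unrounded ratios are
always available.  Note an asymmetry inherited from how such tables are
printed: an efficiency printed next to an already-rounded speedup (S≈63,
N=80 → 79%) is only reproducible from that rounded speedup, not from the
also-rounded times.

The simulator implements greedy list scheduling — an idle worker takes the
next datum in list order; ties break toward the lowest worker index — which
mirrors the engine's one-datum-at-a-time dispatch.  Dispatch order for
queued datums is list order; this is an assumption (the engine makes no
ordering promise beyond determinism of the merged result).  It models pure
processing time only: no container start-up, no transfer costs, no
resource-aware placement.  Its purpose is qualitative: for identical datum
durations it reproduces the closed form makespan = ⌈n/N⌉·d, and for
imbalanced workloads it exhibits the efficiency ceiling
E(N) ≤ min(1, total/(N·max duration)) — the reason measured efficiency
declines as workers are added when a few datums dominate.

## The synthetic fixture

The fixture generator emulates the *topology* of a metabolomics
preprocessing study — per-sample scatter, gather, report — at toy scale.
Samples are CSVs of `(mz, rt, intensity)` triples drawn uniformly from
plausible ranges (m/z 50–1000, retention time 0–900 s, intensity 0–1000
with a filter threshold at 500 so roughly half the rows survive stage 1);
20 peaks per sample by default, 3 samples in the demo, everything a pure
function of `(n_samples, peaks_per_sample, seed)`.  Each sample uses an
independent seeded substream, so adding a sample never perturbs existing
ones — which is what makes the incremental demo honest.

What the fixture does *not* emulate: real spectral data formats, realistic
per-datum runtime imbalance (toy stages run in milliseconds), multi-GB
blobs, or any actual quantification/annotation chemistry.  Passing tests
therefore establish the engine's bookkeeping guarantees — versioning,
incrementality, atomicity, provenance — not the scientific validity of any
particular workflow run on it.

## Problem sizes used in verification

The automated checks use: partition counts at 138 and 5000 files (the
motivating study's per-sample and per-spectrum sizes); 50 randomized
commit histories of 2–3 commits each on a three-stage DAG for the
incremental-vs-from-scratch oracle; exhaustive scheduler cross-validation
over all workloads on durations {1, 2, 5} with n ≤ 8 and N ≤ 4 against an
independent event-driven enumeration.  These sizes exercise every code
path (add/modify/delete, skip/recompute, cascade, carry-forward) while
keeping the whole suite fast enough to run on every change.

## Known limitations

* One linear head per repo; no branches, merges, or concurrent writers.
* One partitioned input per pipeline (plus whole-mounted side inputs); no
  cross/union/join input combinators.
* Constant parallelism only; no cluster-size-scaled worker counts, no
  resource requests, no job retries.
* Subprocess isolation is by directory convention, not containerization:
  a stage command can in principle reach outside its sandbox.
* The append-only store never reclaims space.
* No datum-level provenance below the commit granularity.
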
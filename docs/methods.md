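# Methods

## Threat model and cryptographic construction

The adversary is the central parameter server: it stores and relays
ciphertexts, holds no key, and may modify, replay, or drop what it
serves. Trainers are trusted (cross-silo setting); collusion and
weight-inversion privacy questions are out of scope here.

Weights are protected by encrypt-then-MAC with independent keys:
AES-256-CBC under Ke (32 bytes), then HMAC-SHA512 under Ka (64 bytes)
over `IV ‖ body`, with the full 64-byte tag untruncated. Three choices
deserve justification:

- **The tag covers the IV.** CBC decryption XORs the IV into the first
  plaintext block, so an IV outside the MAC would leave the classic
  malleability attack (`IV⊕r` ⇒ first block `W⊕r`) undetected. The
  attack harness (`cbc_iv_flip_attack`) demonstrates both the attack
  against raw CBC and its rejection by the codec.
- **Verify before decrypt, constant-time compare.** The receiver never
  runs the block cipher on unverified input, so padding oracles cannot
  arise; `hmac.compare_digest` avoids timing leaks on the tag.
- **Padding is PKCS#7** (always at least one byte, so the body length is
  `16·⌈(|m|+1)/16⌉`).

The AES-256 block cipher and CBC mode are implemented in this package
(pure Python, byte-table implementation) and are pinned to the FIPS-197
single-block vector and the NIST SP 800-38A CBC vectors in the test
suite. The implementation favors auditability over speed and makes no
constant-time claims at the table-lookup level; it comfortably handles
the desk-scale bundles the simulator moves (tens of kilobytes,
milliseconds per message).

**Replay** is invisible to the MAC — a replayed ciphertext is authentic.
Each plaintext is therefore framed with a monotone 8-byte upload
counter; a receiver seeing a counter no greater than the last one it
accepted raises a staleness event. This is an extension beyond tag
verification, and it can be disabled (`replay_protection=False`) to
model the bare protocol. A dropped message (server returns ⊥) is
indistinguishable from the protocol's legitimate initial state by
design; the simulator models it but no detection is claimed.

Serialized weight bundles use a deterministic format (entries sorted by
name, little-endian, IEEE-754 binary32), so identical weights always
produce identical bytes — this is what makes the protocol-transparency
check ("server channel = serverless hand-off, bit for bit") meaningful.

## Model composition

A base model M: ℝᵃ→ℝᵇ is extended by a head Mᵢ: ℝᵇ→ℝᶜ; `compose`
verifies the dimension contract and a null head leaves M unchanged
(M∘M₀ = M). A base spec may carry a *feature cut*: layers after the cut
(a pretraining classifier) stay in the stored weight vector W but are
bypassed by the composed forward pass. This mirrors checkpoint reuse in
practice and is why the series model counts 61,101,097 trainable
parameters: the full 1000-class AlexNet (61,100,840, classifier
included) plus a 256→1 head (257), even though the composed forward
path stops at the 256×6×6 feature maps. The multi-label model instead
*replaces* the classifier: DenseNet-121 features + a 1024→14 sigmoid
layer, 6,968,206 parameters. Both counts are checked against
independent per-layer arithmetic oracles in the tests.

The series head applies global average pooling over each slice's 6×6
feature maps, then a maximum over the series axis s (an exam has a
variable number of slices; a finding anywhere in the series should
drive the score), then the linear unit.

Head initialization (unspecified upstream) is He-uniform weights with
zero biases, fully seeded: attaching a head twice with one seed gives
identical V, different seeds give different V.

## The numpy engine

Conv2d (im2col), max/average pooling, linear, ReLU/sigmoid, global
pooling, and the series max implement both forward and backward passes
in float32; gradients are verified against central finite differences.
The DenseNet blocks and batch normalization are inference-only
(running statistics at their initial values): the reference
architectures are built, counted, and run forward, but only the tiny
model family is trained — full-scale training is explicitly outside
the desk-scale scope. Adam (with optional AMSGrad) and SGD with
momentum use classical L2 weight decay added to the gradient.
Parameters behind the feature cut receive no gradient and no decay;
they ride along unchanged, as a checkpointed-but-unused classifier
would.

The tiny trainable family is a two-conv backbone (8 then `base_out`
channels, 3×3 kernels, 2×2 max pools) with a flattened-map classifier
tail for pretraining. Its *series* head max-pools spatially before the
series max: a focal finding occupies a few pixels, and averaging a
coarse feature map dilutes it below learnability for so shallow a
network, while the spatial maximum preserves it. (The full-scale
series head keeps global average pooling, where AlexNet's deep
receptive fields do the concentrating.) The multi-label head scores
the flattened coarse maps, because its synthetic labels are
location-coded and global pooling is location-blind.

## Losses and schedules

Binary series classification uses the prevalence-weighted cross
entropy

    L(X,y) = −w(1)·y·log p − w(0)·(1−y)·log(1−p),
    w(1) = Σpos/Σtotal,  w(0) = 1 − w(1),

with probabilities clamped to [1e−7, 1−1e−7]. With the two knee-MRI
training cohorts (139/552, 208/1130) this gives w(1) ≈ 0.2063. Note
the convention: w(1) multiplies the *positive* term, i.e. the minority
class is **down-weighted** by its prevalence — the reverse of the
usual inverse-prevalence weighting. It is implemented exactly in that
form; a `conventional=True` switch swaps the weights and is off by
default.

The multi-label loss is the plain sum of 14 per-class binary cross
entropies. Learning-rate schedules: step decay from the initial rate,
lr(ce) = lr₀·0.5^⌊ce/2⌋ (read as decay from lr₀; compounding the
update on the current rate every epoch would collapse it far faster
than any standard schedule), and reduce-on-plateau (factor 0.3,
patience 5 central epochs, monitoring validation loss — the monitored
quantity is configurable since checkpoint selection by validation loss
is the stated practice).

Early sharing splits a trainer's local indices uniformly at random
into 20 near-equal parts (a quarter of 78,468 images → 17 parts of 981
and 3 of 980; integer part 980) and shares weights after one pass per
part, reducing drift toward any single non-iid shard.

AUC is the Mann–Whitney rank statistic with ties counted ½, tested
against brute-force pair counting.

## Synthetic data

The generators reproduce the *statistical skeleton* of the study data,
not its photometry: variable-length single-channel series (s uniform
in 1–3 by default, 32×32 pixels) with imbalanced binary labels
(default positive fraction 208/1130), where positives carry a bright
Gaussian blob (amplitude `signal_strength`, σ ≈ 3–4 px) in at least
one slice over a smooth random background with pixel noise (σ = 0.05);
multi-label images with one blob site per label (labels independent
Bernoulli, default prevalence 0.1); a balanced multi-class pretraining
corpus whose classes are blob *locations*, drawn from the same blob
family so pretraining learns transferable blob detection; independent
label flips at a given rate with an auditable mask; and label-skewed
Dirichlet splits for non-iid sharding. Everything is bit-reproducible
from a seed.

What passing tests on this data do and do not show: they validate the
protocol, the codec, the composition/training machinery, and that the
planted signal is learned end-to-end; they say nothing about real MRI
or radiograph performance, which requires the original datasets and
GPU-scale training and is explicitly out of scope.

## Desk-scale study conditions

The end-to-end run uses 3 trainers (1 vertical + 2 horizontal), the
tiny CNN, 100 exams per horizontal trainer, 100 held-out exams,
positive fraction 0.3, signal strength 0.8, Adam at lr 2e−3, and 4
central epochs (~4 s on one CPU core). Two of these deserve comment:

- **Positive fraction 0.3** rather than the full-scale 208/1130
  ≈ 0.18. Under the printed minority-down-weighted loss, learning at
  0.18 prevalence needs far more steps than a desk-scale budget
  provides — even a convex logistic-regression oracle on extracted
  features stalls — while at 0.3 the task is learnable in a few
  epochs. The generator default remains 208/1130.
- **The vertical phase runs 3 local epochs.** The at-most-two rule
  governs the shared horizontal schedule; pretraining precedes any
  sharing and corresponds to fully training M upstream.

The noisy-label study compares paired runs (identical data, schedule,
seeds) with and without vertical pretraining at 10% label flips, in a
scarcer regime (40 exams/trainer, signal 0.5) where transfer has room
to matter. Across seeds the pretrained arm wins on average (mean AUC
difference ≈ +0.19 over seeds 0–5), but single seeds can invert — the
pinned-seed test therefore asserts the difference only up to a 0.02
tolerance and the effect should be read as typical, not certain, at
this scale.

## Schedules and accounting

`make_schedule` draws a turn order in which every trainer appears
exactly `central_epochs` times and no trainer takes more than two
consecutive turns, by greedy sampling with a feasibility guard
(trainer j remains placeable iff rem(j) ≤ 2·(others+1), adjusted for
the current run); validity is property-checked over 10,000 seeds.
Consecutive identical turns merge into one round of two local epochs.

Communication accounting sums actual encoded ciphertext bytes per
trainer and direction; a per-message override projects full-scale
traffic (234 MB bundles × 20 central epochs × up+down = 9.36 GB per
trainer; 28 MB × 4 trainers × 15×20 early-sharing uploads ≈ 33.6 GB).
The serialized 61.1M-parameter bundle is 244,404,388 payload bytes
(≈ 233 MiB), consistent with the reported ~234 MB checkpoint; the
ciphertext adds only IV, padding, and tag, so "the ciphertext is also
~234 MB" is treated as the approximation it is.

## Known limitations

- Reference architectures are not trainable in this engine (by scope).
- The pure-Python cipher is not hardened against cache-timing
  adversaries and is desk-scale slow (~4 s per encrypted MB).
- Detection triggers a halt; recovery/resync policies are stubs.
- The synthetic task is far easier than real imaging; AUC numbers from
  the simulator characterize the machinery, not clinical performance.
- Byzantine trainers, differential privacy, and key management are out
  of scope.
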
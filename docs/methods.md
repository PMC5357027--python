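# Methods

## The model

`trialchain` models clinical-trial record keeping as a transactional,
inter-organisational ledger between mutually untrusting parties: a
regulator (e.g. a national medicines agency), sponsors, and the contract
research organisations (CROs) that run trials.  Two contract types form a
hierarchy:

* **Regulator contract** — owned by the regulator identity that deployed
  it.  Holds clinical trial authorisations (CTAs: trial id, sponsor,
  authorised CRO address, deployment window) and the container of trial
  contracts deployed under them.  CTA registration is owner-only; the
  off-chain licensing agreement is assumed concluded before registration,
  so a registered CTA is stored `approved`.
* **Trial contract** — created through the regulator contract by the CRO
  named in an approved CTA, within the CTA's window.  Owns the protocol
  (content hash of the full document, endpoint list, recruitment window,
  trial end date), the subject container and, per subject, an append-only
  list of timestamped clinical measurements.

The permissioning rules are the protocol itself, made executable:

1. no subject may be stored before the protocol and its endpoints are
   deposited (`PROTOCOL_REQUIRED`);
2. enrolment is confined to the recruitment window (`WINDOW_CLOSED`);
3. measurements stop at the trial end date (`TRIAL_ENDED`);
4. the protocol is immutable from first deposition — there is no call
   that edits or deletes anything, so endpoint switching is structurally
   impossible (`PROTOCOL_IMMUTABLE`);
5. only the CTA's authorised CRO can create the trial (`CRO_MISMATCH`),
   and only the trial owner can write to it (`OWNER_ONLY`).

All window comparisons are **closed intervals** (`[start, end]`
inclusive): a call at exactly the boundary timestamp is accepted, one
second later is rejected.  Rules are judged against the **block**
timestamp of inclusion, never a sender-claimed time; a sender-side
timestamp is still carried (signed) on every transaction for provenance.
The check order inside each call is fixed and documented in
`contracts.py`, because adversarial tests need a decidable expected code
when several rules are violated at once.

## Ledger design

* **Consensus**: single-authority sealing (proof-of-authority).  The
  network being modelled is private and permissioned, so mining and fork
  choice add nothing; the sealer set is fixed in the genesis
  configuration, and finality is inclusion in a sealed block.  The
  read-side `--confirmations` flag reports state only up to tip − k for
  users who want a finality margin; it defaults to 0 because a
  single-sealer chain cannot reorganise.
* **Hashes**: SHA-256 everywhere (transaction hashes, Merkle roots, block
  hashes, content addresses), so a protocol document's store address is
  the same digest that appears in transaction arguments.
* **Addresses**: last 20 bytes of SHA-256 of the encoded public key,
  lowercase hex.
* **Signatures**: Ed25519, implemented in-repo from RFC 8032 in pure
  Python and pinned by the RFC's test vectors.  Deterministic signatures
  are essential: with a seeded workload and logical timestamps, the same
  seed produces a byte-identical chain, which the determinism check
  asserts at file level.  Verification caches radix-16 multiplication
  tables per public key (a chain has few identities and many signatures)
  and memoises verified (key, message, signature) triples, which is what
  makes exhaustive tamper sweeps affordable.
* **Canonical serialization**: type-tagged, length-prefixed encoding with
  lexicographically sorted map keys and minimal varints; the decoder is
  strict, so the encoding is injective in both directions.  Floats are
  rejected in hashed content to avoid cross-platform formatting drift;
  measurements carry their numbers inside an opaque JSON string.
* **Commitment layering**: the signature binds (sender, nonce,
  sender_time, call); `tx_hash` is the digest of the whole signed
  transaction *including signature bytes*; the Merkle root (pairwise
  SHA-256, odd node duplicated, empty block → digest of the empty string)
  commits to the ordered tx hashes; the block hash commits to the header;
  `prev_hash` links blocks.  Every byte of a serialized transaction is
  therefore covered by a cheap hash recomputation, with the signature
  check as the semantic backstop.
* **Nonces** are per-sender and strictly consecutive (1, 2, 3, …) in
  chain order, giving replay protection; a rejected transaction does not
  consume its nonce because it is excluded at sealing.  Failed
  transactions are excluded and *reported* with a failure code rather
  than included-with-revert — simpler than gas/revert semantics and it
  keeps every stored transaction rule-valid under replay.
* **State queries**: `state_at(chain, h)` is a pure replay of blocks
  0..h.  `iter_states` yields every height in one incremental pass —
  equivalent (asserted in tests) but O(n) overall, which is what the
  per-height sweeps use on the ~2,100-transaction chain.

## Payload encryption

Where data privacy is required, measurement payloads are sealed to a
per-trial regulator public key before submission: an ephemeral curve
keypair per message, Diffie-Hellman against the recipient key on the same
Edwards curve as the signatures, and HMAC-SHA256 as keystream and
authentication tag.  The regulator files one private key per trial
contract; decrypting a box with another trial's key fails its tag check.
The public key travels in the CTA record and is copied into the trial
contract at creation, so no extra contract call is needed.  Encryption is
randomised: equal payloads seal to distinct ciphertexts.

## The synthetic workload

No external dataset exists for this artifact; the generator *is* the
study condition.  It emulates an influenza-drug (oseltamivir-style) trial
programme:

* schedule in logical ticks of one day (86,400 s), one block per tick,
  epoch fixed at 1,600,000,000 POSIX s — timestamps are injected, never
  read from the system clock, so runs are reproducible;
* ticks 0–3: regulator deploys, registers one CTA per trial
  (deployment window ticks 1–3), CROs create trials and deposit
  protocols; recruitment spans ticks 4–8; each subject then contributes
  one visit per day until their visit count is reached; the trial end
  date leaves one margin day after the last possible visit;
* endpoints: primary *time to alleviation of symptoms* (hours),
  secondary *incidence of secondary complications*;
* visit values are log-normal, mu = 4.4998, sigma = 0.35 (median ≈ 90 h,
  the scale of reported symptom-duration outcomes in influenza treatment
  trials); the parameters are recorded in the workload header and no test
  depends on the specific numbers;
* the paper-scale preset is 2 trials × 50 subjects × 20 visits
  = 2,107 transactions (1 deploy + 3 calls per trial + 100 enrolments
  + 2,000 measurements), matching the qualitative scale of "thousands of
  transactions"; the default small workload is 1 × 10 × 5 = 64 calls.

With `adversarial_fraction` f > 0, the generator injects
round(f · (enrolments + measurements)) extra events cycling through five
violation classes — late enrolment, post-end measurement, pre-protocol
enrolment, endpoint re-definition, wrong-CRO trial creation — each
labelled with the exact failure code it must be rejected with.  The
labels come from a small rule simulation *inside the generator*, written
independently of the contract engine (labels and a minimal dict state, no
addresses, hashes or signatures), so replaying a workload cross-checks
two implementations of the same rules; agreement is asserted over many
seeds.

What the generator does **not** emulate: pharmacologically realistic
efficacy or dropout, protocol amendments, multi-regulator governance,
network latency or concurrent submission races.  Passing tests therefore
demonstrate the integrity and permissioning mechanics, not clinical
realism of the data values.

## Tamper-evidence measurement

The exhaustive sweep (`mutation.py`) serializes every transaction and
block header canonically and mutates every byte, one at a time (each byte
replaced by (b+1) mod 256).  A mutation counts as detected if the mutated
bytes no longer strictly decode to a well-formed record — a ledger a node
would refuse to parse — or if re-auditing flags a failure.  Because
replacing a transaction or header in block k can only affect the audit
checks of block k (plus k+1's linkage reads for headers), the sweep
re-verifies just those blocks against precomputed state snapshots; sampled
mutations are cross-checked against the unabridged `verify_chain` in the
test suite.  On the 64-call seed-1 chain this is ~39,700 mutations.

## Numerical and degenerate-input choices

* Empty blocks are permitted; their Merkle root is the digest of the
  empty byte string (documented sentinel).  A single-leaf tree still
  hashes one round (leaf paired with itself).
* Genesis is block 0, all-zero `prev_hash`, no transactions.
* Contract addresses are a pure function of (deployer address, nonce), so
  clients can compute an address before the deploying block is sealed.
* `seal_block` refuses an unauthorised sealer or a timestamp regression
  outright (exception), but never drops a bad transaction silently —
  rejections are returned with codes.
* Encryption/decryption distinguishes reused peers (cached multiplication
  table) from one-shot ephemeral points (plain double-and-add), purely a
  performance trade.

## Known limitations and extension points

* Protocol amendments: real trials amend protocols under regulatory
  approval.  The strict immutable-from-first-deposition rule is the safer
  reading of the endpoint-switching problem; regulator-approved
  versioning would be the natural extension.
* Single sealer: resilience of the regulator's sealing key is out of
  scope, as are peer-to-peer transport, mempool gossip and forks.
* The content-addressed store is a local directory sharing the ledger's
  SHA-256 addressing; it does not replicate or pin.
* Problem sizes in the test suite and acceptance script (paper-scale
  2×50×20 chain, 64-call tamper-sweep chain, 20-seed oracle comparison,
  300–1,000 encryption round trips) are the package's chosen defaults for
  routine verification; all generators scale up by parameter.
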
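# trialchain

A permissioned, tamper-evident ledger with smart-contract rules for
clinical-trial data transparency.

Clinical-trial evidence is routinely weakened by missing data, endpoint
switching, data dredging and selective publication.  `trialchain` is a
self-contained implementation of the countermeasure: trial conduct is
recorded as signed, timestamped transactions on an append-only hash chain,
and the trial protocol's rules are enforced *by the ledger itself* through
two contract state machines:

* a **regulator contract** holding clinical trial authorisations (CTAs)
  and the container of trial contracts deployed under them;
* per-trial **trial contracts**, owned by the authorised CRO, holding the
  protocol (document hash, endpoints, recruitment window, end date), the
  enrolled subjects and their successive clinical measurements.

No subject can be stored before the protocol and endpoints are deposited;
no enrolment outside the recruitment window; no measurement after the
trial end; and the protocol is immutable from first deposition — there is
no call that edits or removes anything, so endpoint switching is
structurally impossible.  Every record is Ed25519-signed by its sender
(resolvable to a CRO), nonce-protected against replay, and committed
through SHA-256 transaction hashes, Merkle roots and hash-linked block
headers, so flipping any single byte of trial history is detectable.
Protocol and consent documents live in a content-addressed store; their
on-chain hashes double as proof-of-existence anchors.  The complete state
— trials underway, subjects recruited, every data point with sender and
timestamp — is queryable at any historic block.

The audience is anyone studying research-transparency infrastructure:
the package is a faithful, fully testable model of the regulator/CRO
workflow, not a deployment client for a public network.

## Worked example

Generate a synthetic influenza-trial workload (1 trial, 10 subjects,
5 visits each — 64 contract calls), seal it one block per day, and read
everything back:

```console
$ trialchain run-workload --seed 1 --subjects 10 --measurements 5
ran 64 events: 64 accepted, 0 rejected, chain height 14
a81f387e91d6b7e946ebc96fb3fc489e28d5a4d5b95a9941e6c4cb38ff2a3871

$ trialchain summary
height 14: 1 trial(s)
trial OSLT-001 at 8019c7ec6facb5b358266e95a05aa92dafcde6dc — CRO 9eee3be8de387a957722cff38457325d711d6214
  protocol 870601f7ee9f405e5bfcc08faecaac824c1b2cda2bff12d735b36d11b6976174
  endpoints: time_to_alleviation_of_symptoms, incidence_of_secondary_complications
  subjects: 10
    OSLT-001-S001 enrolled at 1600345600: 5 measurement(s) [1600432000..1600777600]
    ...
```

The first line of output is the tip block hash — rerunning with the same
seed reproduces it byte for byte.  The summary shows, per trial, the
owning CRO's address, the protocol document's content hash, the
pre-specified endpoints, and each subject's enrolment and measurement
timestamps (block times, daily ticks from the workload epoch).

Audit the chain and query a historic block (before recruitment opened, no
subjects exist yet):

```console
$ trialchain audit
VALID

$ trialchain summary --at-block 4 | head -1
height 4: 1 trial(s)
```

Prove the protocol document existed, unmodified, when the trial was
created — block 3 here, before any subject was enrolled:

```console
$ trialchain prove store/87/870601f7…976174
870601f7…976174: anchored in block 3 at timestamp 1600172800 (tx b7781425…e328c)
```

Editing a single hex digit anywhere in `ledger/chain.jsonl` flips `audit`
to `INVALID` with the block/transaction coordinates of the change.

The same flow is available step by step (`keygen`, `init`, `submit`,
`seal`) and as a library (`trialchain.ledger`, `trialchain.contracts`,
`trialchain.documents`, `trialchain.workload`); see `docs/methods.md` for
the model, rules and design choices.

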
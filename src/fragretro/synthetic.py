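"""Desk-scale synthetic corpora for end-to-end exercise of the pipeline.

Real reaction corpora are large and external; these generators produce
product→reactant corpora with the statistical structure the translation
method assumes — a deterministic, learnable transformation of curated
key sets — so curation, training, evaluation and retrieval all run from
nothing but a seed.

Products are real drug-like molecules (a packaged list of ~250 small
SMILES, optionally decorated with random substituents for diversity).
Reactions are *toy rules* acting directly on key sets: remove a few keys,
add a few keys, optionally split the set into two reactants.  Which rule
fires is a deterministic function of the product's keys (the presence of a
selector key), so the product→reactant map is a function — a property the
curated real dataset is forced to have via injective collapse.  The rules
make no claim of chemical realism; after encoding, the translation
machinery never inspects atoms, so key-level rules exercise it fully.

Contamination (duplicates, internal twins, 3-reactant records, over-long
pairs, injectivity violations) can be planted at known rates to test that
the curation cascade removes exactly what it should.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem

from .corpus import ReactionRecord
from .keys import Backend, KeySet, compute_maccs, profile_keys
from .vocab import (SEP, KeyVocabulary, build_vocabulary, curate_keys,
                    encode_molecule, encode_reactants)

__all__ = ["BASE_MOLECULES", "ToyRule", "SyntheticCorpus", "make_molecule_corpus",
           "default_rules", "apply_rules", "make_reaction_corpus",
           "fixture_vocabulary"]

# ~250 small, valid, drug-like molecules and common fragments/reagents.
BASE_MOLECULES: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "CC(=O)Nc1ccc(O)cc1",
    "Clc1ccccc1-c1nc2ccccc2[nH]1", "c1ccc2c(c1)oc1ccccc12",
    "c1ccc2c(c1)sc1ccccc12", "c1ccc2[nH]c3ccccc3c2c1",
    "OCC1OC(O)C(O)C(O)C1O", "NC(Cc1ccccc1)C(=O)O",
    "NC(Cc1c[nH]c2ccccc12)C(=O)O", "NC(Cc1ccc(O)cc1)C(=O)O",
    "OC(=O)C1CCCN1", "NCCc1ccc(O)c(O)c1", "NCCc1c[nH]c2ccccc12",
    "CN1CCC(CC1)=C1c2ccccc2CCc2ccccc21", "CC(N)Cc1ccccc1",
    "CNC(C)Cc1ccccc1", "OC(=O)c1ccccc1O", "OC(=O)c1ccccc1N",
    "Nc1ccc(cc1)S(N)(=O)=O", "CC1=CC(=O)C=CC1=O", "Oc1ccc2ccccc2c1",
    "Nc1ccc2ccccc2c1", "OC(=O)c1cccnc1", "OC(=O)c1ccncc1",
    "c1ccc(nc1)-c1ccccn1", "Cc1ccccc1C", "Cc1ccc(C)cc1",
    "COc1ccc(CCN)cc1", "COc1cc2c(cc1OC)CCN2", "CN1CCN(CC1)c1ccccc1",
    "O=C1CCCCC1", "O=C1CCCCCC1", "OC1CCCCC1", "NC1CCCCC1",
    "C1CCOC1", "C1CCNC1", "C1CCSC1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "Oc1ccc[nH]1", "Cc1ccco1", "Cc1cccs1", "Cc1ccc[nH]1",
    "O=Cc1ccco1", "O=Cc1cccs1", "CC(=O)c1ccccc1", "CC(O)c1ccccc1",
    "OCc1ccccc1", "NCc1ccccc1", "ClCc1ccccc1", "BrCc1ccccc1",
    "N#Cc1ccccc1", "O=[N+]([O-])c1ccccc1", "Fc1ccccc1", "Clc1ccccc1",
    "Brc1ccccc1", "Ic1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "COc1ccccc1",
    "CSc1ccccc1", "CNc1ccccc1", "CN(C)c1ccccc1", "CC(=O)Nc1ccccc1",
    "O=C(O)c1ccccc1", "O=C(Cl)c1ccccc1", "COC(=O)c1ccccc1",
    "CCOC(=O)c1ccccc1", "NC(=O)c1ccccc1", "O=S(=O)(Cl)c1ccccc1",
    "NS(=O)(=O)c1ccccc1", "O=Cc1ccccc1", "C=Cc1ccccc1", "C#Cc1ccccc1",
    "CCc1ccccc1", "CCCc1ccccc1", "CC(C)c1ccccc1", "CC(C)(C)c1ccccc1",
    "FC(F)(F)c1ccccc1", "c1ccc(cc1)-c1ccccc1", "c1ccc(cc1)Cc1ccccc1",
    "c1ccc(cc1)Oc1ccccc1", "c1ccc(cc1)Sc1ccccc1", "c1ccc(cc1)Nc1ccccc1",
    "O=C(c1ccccc1)c1ccccc1", "O=C(Nc1ccccc1)c1ccccc1",
    "O=C(Oc1ccccc1)c1ccccc1", "c1ccc2ncccc2c1", "c1ccc2cnccc2c1",
    "c1ccc2ccncc2c1", "Oc1ccc2ncccc2c1", "Cc1ccc2ncccc2c1",
    "c1ccc2[nH]ccc2c1", "Cc1c[nH]c2ccccc12", "O=c1cc[nH]c(=O)[nH]1",
    "Cc1cc(=O)[nH]c(=O)[nH]1", "Nc1ncnc2[nH]cnc12", "O=c1[nH]cnc2[nH]cnc12",
    "Nc1nc2[nH]cnc2c(=O)[nH]1", "c1ncc2[nH]cnc2n1", "c1cnc2[nH]ccc2c1",
    "Cn1ccnc1", "c1cnc[nH]1", "Cn1ccnc1C", "c1cscn1", "Cc1nccs1",
    "Cc1cscn1", "NC(=O)c1cscn1", "c1cocn1", "Cc1occc1C", "c1cnoc1",
    "Cc1cc(C)on1", "Cc1cc(C)no1", "c1cn[nH]c1", "Cc1cc(C)n[nH]1",
    "Cc1ccn[nH]1", "c1cnncc1", "c1cnncn1", "c1cncnc1", "Nc1ccncn1",
    "Nc1ncccn1", "Nc1nccnc1", "Cc1ncccn1", "Cc1cnccn1", "Oc1ccncn1",
    "Oc1ncccn1", "CC1CCCCC1", "CC1CCCC1", "CC1CCC1", "C1CC1", "C1CCC1",
    "C1CCCC1", "C1CCCCC1", "C1CCCCCC1", "C1CCC2CCCCC2C1",
    "C1CCC2(CC1)CCCCC2", "C1CC2CCC1CC2", "OC(=O)CCC(=O)O",
    "OC(=O)CC(=O)O", "OC(=O)C=CC(=O)O", "OC(=O)CCCCC(=O)O", "NCCCCCN",
    "NCCCCN", "OCCO", "OCCCO", "OCCN", "NCCN", "OCCOCCO", "CC(O)CO",
    "OCC(O)CO", "CC(=O)CC(C)=O", "CC(=O)CC(=O)OCC", "CCOC(=O)CC(=O)OCC",
    "CC(=O)OC", "CC(=O)OCC", "CCOC(C)=O", "CC(=O)N(C)C", "CC(=O)NC",
    "CC(N)=O", "CC#N", "CCO", "CCN", "CCS", "CCOCC", "CCNCC", "CC(C)O",
    "CC(C)N", "CC(C)=O", "CC(C)C(=O)O", "CCC(=O)O", "CCCC(=O)O",
    "CC(C)CC(=O)O", "CC(=O)O", "OC=O", "C(=O)N", "CCC#N", "CC(C)CO",
    "CC(C)CN", "CCCCO", "CCCCN", "CCCCC(=O)O", "CCCCCC", "CCCCCCO",
    "CC=CC(=O)O", "CC=CC=O", "C=CC(=O)O", "C=CC#N", "C=CCO", "C=CCBr",
    "ClCCCl", "ClCC(=O)O", "FC(F)(F)C(=O)O", "OCC(F)(F)F", "NCC(F)(F)F",
    "CSC", "CS(C)=O", "CS(C)(=O)=O", "CNC", "CN(C)C", "CNC(N)=O",
    "NC(N)=O", "NC(=S)N", "NC(=N)N", "COC(=O)C(C)N",
    "CC(C)(C)OC(=O)NC(C)C(=O)O", "CC(C)(N)C(=O)O", "OC1CCNC1",
    "OC1CCNCC1", "NC1CCNCC1", "O=C1CCCN1", "O=C1CCCCN1", "O=C1CCCO1",
    "O=C1CCCCO1", "CN1CCCC1", "CN1CCCCC1", "CN1CCOCC1", "C1COCCN1",
    "C1CNCCN1", "CN1CCNCC1", "O1CCOCC1", "CC1COC(C)O1", "Oc1ccc(Cl)cc1",
    "Oc1ccc(Br)cc1", "Oc1ccc(F)cc1", "Oc1ccc(C)cc1", "Oc1ccc(OC)cc1",
    "Oc1ccc(N)cc1", "Oc1ccc(cc1)C(=O)O", "Oc1ccc(C=O)cc1",
    "Nc1ccc(Cl)cc1", "Nc1ccc(C)cc1", "Nc1ccc(OC)cc1", "Nc1ccc(cc1)C(=O)O",
    "Nc1ccc(cc1)[N+](=O)[O-]", "Clc1ccc(Cl)cc1", "Clc1ccc(cc1)C(=O)O",
    "Clc1ccc(C=O)cc1", "Cc1ccc(cc1)C(=O)O", "Cc1ccc(C=O)cc1",
    "Cc1ccc(cc1)S(=O)(=O)O", "Cc1ccc(cc1)S(=O)(=O)Cl", "COc1ccc(C=O)cc1",
    "COc1ccc(cc1)C(=O)O", "COc1ccc(CC=O)cc1", "COc1ccc(CCO)cc1",
)

_SUBSTITUENTS = ("C", "CC", "O", "N", "CO", "CN", "F", "Cl", "Br",
                 "C(F)(F)F", "C#N", "C(C)C", "OC", "NC", "C(=O)O")


def _decorate(smiles: str, rng: random.Random) -> str:
    """Attach a random substituent to a random H-bearing heavy atom."""
    mol = Chem.MolFromSmiles(smiles)
    sub = Chem.MolFromSmiles(rng.choice(_SUBSTITUENTS))
    combo = Chem.RWMol(Chem.CombineMols(mol, sub))
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetNumImplicitHs() > 0]
    sub_sites = [a.GetIdx() + mol.GetNumAtoms() for a in sub.GetAtoms()
                 if a.GetNumImplicitHs() > 0]
    if not sites or not sub_sites:
        return smiles
    combo.AddBond(rng.choice(sites), sub_sites[0], Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    except Exception:
        return smiles


def make_molecule_corpus(n: int, seed: int, decorate: bool = True) -> list[str]:
    """``n`` seeded draws from the packaged molecule list, optionally with
    0–2 rounds of random substituent decoration.  All outputs parse."""
    rng = random.Random(f"molcorpus:{seed}")
    out = []
    for _ in range(n):
        smi = rng.choice(BASE_MOLECULES)
        if decorate:
            for _ in range(rng.randint(0, 2)):
                smi = _decorate(smi, rng)
        out.append(smi)
    return out


def fixture_vocabulary(molecules: list[str], max_keys: int = 126) -> KeyVocabulary:
    """Curated lettered vocabulary built from a molecule corpus.

    Keys occurring in the corpus survive (up to ``max_keys``, keeping the
    most frequent); ranks and words follow the standard scheme.
    """
    profile = profile_keys(molecules, Backend.MACCS)
    retained = curate_keys(profile, rare_primary=0.0, rare_reference=0.0)
    if len(retained) > max_keys:
        retained = sorted(sorted(retained, key=lambda k: (-profile.count(k), k))
                          [:max_keys])
    return build_vocabulary(retained, profile)


@dataclass(frozen=True)
class ToyRule:
    """Deterministic key-set transformation standing in for a reaction rule.

    Fires when ``selector`` is present in the product key set (``None`` =
    default rule).  ``remove``/``add`` edit the key set; ``split_low``, when
    given, partitions the result into two reactants (keys inside /
    outside ``split_low``), falling back to a single reactant if a side
    would be empty.
    """

    rule_id: str
    selector: int | None
    remove: frozenset[int] = frozenset()
    add: frozenset[int] = frozenset()
    split_low: frozenset[int] | None = None

    def transform(self, keyset: KeySet) -> tuple[KeySet, ...]:
        keys = (set(keyset.indices) - self.remove) | self.add
        if self.split_low is not None:
            lo = keys & self.split_low
            hi = keys - self.split_low
            if lo and hi:
                return (KeySet(lo, keyset.backend), KeySet(hi, keyset.backend))
        return (KeySet(keys, keyset.backend),)


def default_rules(vocab: KeyVocabulary, n_rules: int = 5) -> list[ToyRule]:
    """Five rules over a vocabulary: selectors are moderately frequent keys,
    added keys are drawn from the rare end (so additions really change the
    set), and two rules split the product into two reactants."""
    ranked = sorted(vocab.retained_keys, key=lambda k: vocab.rank[k])
    m = len(ranked)
    sel = [ranked[int(m * f)] for f in (0.12, 0.25, 0.38, 0.5)]
    pool = ranked[int(m * 0.65):]
    # two-reactant split: the most frequent half of the vocabulary goes to
    # one reactant, the rest to the other (a prefix/suffix cut of the
    # rank-ordered sentence)
    split_low = frozenset(ranked[:m // 2])
    rules = [
        ToyRule("r1", sel[0], remove=frozenset({sel[0]}),
                add=frozenset({pool[0], pool[1]})),
        ToyRule("r2", sel[1], remove=frozenset({sel[1]}),
                add=frozenset({pool[2]}), split_low=split_low),
        ToyRule("r3", sel[2], remove=frozenset({sel[2], sel[3]}),
                add=frozenset({pool[3]})),
        ToyRule("r4", sel[3], add=frozenset({pool[4], pool[5]}),
                split_low=split_low),
        ToyRule("r5", None, add=frozenset({pool[6]})),
    ]
    return rules[:n_rules]


def apply_rules(rules: list[ToyRule], keyset: KeySet) -> tuple[ToyRule, tuple[KeySet, ...]]:
    """First rule whose selector is present fires; the last rule must be a
    default (selector ``None``)."""
    for rule in rules:
        if rule.selector is None or rule.selector in keyset:
            return rule, rule.transform(keyset)
    raise ValueError("no applicable rule (rule list lacks a default)")


@dataclass
class SyntheticCorpus:
    records: list[ReactionRecord]                 # contaminated + shuffled
    clean_records: list[ReactionRecord]
    rule_labels: list[str]                        # aligned with clean_records
    product_keysets: list[KeySet]
    reactant_keysets: list[tuple[KeySet, ...]]
    planted: dict[str, int] = field(default_factory=dict)
    vocab: KeyVocabulary | None = None


def make_reaction_corpus(n: int, rules: list[ToyRule], seed: int,
                         vocab: KeyVocabulary,
                         twin_rate: float = 0.0, dup_rate: float = 0.0,
                         multi_reactant_rate: float = 0.0,
                         long_rate: float = 0.0, inject_rate: float = 0.0,
                         molecules: list[str] | None = None,
                         max_pair_length: int = 96,
                         min_keys: int = 6) -> SyntheticCorpus:
    """``n`` unique clean product→reactant records plus planted contamination.

    Clean records: sample a product molecule, restrict its MACCS keys to the
    vocabulary, fire the applicable rule, encode both sides.  Products whose
    records would be twins, duplicates, too long, or too key-poor are
    rejected and resampled, so the clean corpus is guaranteed to survive
    curation untouched.  Contamination of each kind is planted with the
    given per-record rates and its exact planted counts are returned.
    """
    rng = random.Random(f"rxncorpus:{seed}")
    mols = molecules if molecules is not None else make_molecule_corpus(
        max(4 * n, 200), seed=seed * 7 + 1)
    seen_sources: set[tuple[str, ...]] = set()
    clean: list[ReactionRecord] = []
    labels: list[str] = []
    pkeys: list[KeySet] = []
    rkeys: list[tuple[KeySet, ...]] = []
    attempts = 0
    max_attempts = 300 * n + 1000
    i = 0
    while len(clean) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not generate {n} unique records ({len(clean)} found); "
                "increase the molecule pool or lower n")
        if i >= len(mols):
            mols = mols + make_molecule_corpus(2 * n + 100,
                                               seed=seed * 31 + attempts)
        smi = mols[i]
        i += 1
        ks = compute_maccs(smi).restrict(vocab.retained_keys)
        if len(ks) < min_keys:
            continue
        src = tuple(encode_molecule(ks, vocab))
        if src in seen_sources:
            continue
        rule, reactants = apply_rules(rules, ks)
        tgt = tuple(encode_reactants(reactants, vocab))
        if tgt == src:            # change invisible at key resolution
            continue
        if len(src) + len(tgt) > max_pair_length:
            continue
        seen_sources.add(src)
        clean.append(ReactionRecord(product_smiles=smi, reactant_smiles=(),
                                    source_sentence=src, target_sentence=tgt))
        labels.append(rule.rule_id)
        pkeys.append(ks)
        rkeys.append(reactants)

    contaminated: list[ReactionRecord] = list(clean)
    planted = {"duplicates": 0, "twins": 0, "multi_reactant": 0,
               "too_long": 0, "injective_extras": 0}

    for rec in clean:
        if rng.random() < dup_rate:
            contaminated.append(rec)
            planted["duplicates"] += 1

    def fresh_source() -> tuple[tuple[str, ...], KeySet] | None:
        nonlocal i
        for _ in range(2000):
            if i >= len(mols):
                mols.extend(make_molecule_corpus(500, seed=seed * 13 + i))
            smi_ = mols[i]
            i += 1
            ks_ = compute_maccs(smi_).restrict(vocab.retained_keys)
            if len(ks_) < min_keys:
                continue
            src_ = tuple(encode_molecule(ks_, vocab))
            if src_ in seen_sources:
                continue
            seen_sources.add(src_)
            return src_, ks_
        return None

    for rec in clean:
        if rng.random() < twin_rate:
            got = fresh_source()
            if got is None:
                break
            src, _ = got
            contaminated.append(ReactionRecord(None, (), src, src))
            planted["twins"] += 1

    for rec in clean:
        if rng.random() < multi_reactant_rate:
            got = fresh_source()
            if got is None:
                break
            src, ks = got
            keys = ks.sorted()
            third = max(len(keys) // 3, 1)
            parts = [KeySet(keys[:third], ks.backend),
                     KeySet(keys[third:2 * third], ks.backend),
                     KeySet(keys[2 * third:], ks.backend)]
            if any(len(p) == 0 for p in parts):
                continue
            tgt = tuple(encode_reactants(parts, vocab))
            contaminated.append(ReactionRecord(None, (), src, tgt))
            planted["multi_reactant"] += 1

    for rec in clean:
        if rng.random() < long_rate:
            got = fresh_source()
            if got is None:
                break
            src, _ = got
            tokens = list(src)
            tgt = list(src)
            while len(src) + len(tgt) + 1 <= 100:
                tgt.extend(tokens)
            tgt = tuple(list(src) + [SEP] + tgt[:101])
            contaminated.append(ReactionRecord(None, (), src, tgt))
            planted["too_long"] += 1

    for rec in clean:
        if rng.random() < inject_rate:
            # same source, strictly longer distinct target -> collapsed later
            extra = tuple(list(rec.target_sentence) + [rec.source_sentence[0]])
            if len(rec.source_sentence) + len(extra) > 100:
                continue
            if extra == rec.source_sentence:   # would be removed as a twin instead
                continue
            contaminated.append(ReactionRecord(None, (), rec.source_sentence, extra))
            planted["injective_extras"] += 1

    rng.shuffle(contaminated)
    return SyntheticCorpus(records=contaminated, clean_records=clean,
                           rule_labels=labels, product_keysets=pkeys,
                           reactant_keysets=rkeys, planted=planted, vocab=vocab)


def make_reaction_smiles_lines(n: int, seed: int, malformed: int = 0) -> list[str]:
    """Toy ``reactants>reagents>product`` lines from packaged molecules
    (chemically arbitrary; for parser and file-level tests).  Optionally
    appends ``malformed`` unparseable lines."""
    rng = random.Random(f"rxnsmiles:{seed}")
    lines = []
    for _ in range(n):
        r = rng.sample(BASE_MOLECULES, rng.randint(1, 2))
        p = rng.choice(BASE_MOLECULES)
        reagent = rng.choice(("", rng.choice(BASE_MOLECULES)))
        lines.append(f"{'.'.join(r)}>{reagent}>{p}")
    for j in range(malformed):
        lines.append("not_a_smiles>>also(bad" if j % 2 else "CCO.CC(=O)O")
    return lines
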
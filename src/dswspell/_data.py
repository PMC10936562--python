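"""Embedded study data: the 60-entry Dyslexic Sight Words (DSW) lexicon with
hand-encoded syllabification/stress metadata, the annotated misspelled forms
with their expert category labels, the per-word correct/incorrect counts for
both groups, and the per-grade incorrect-word totals.

Syllable metadata is stored as per-syllable grapheme-UNIT lengths (digraphs
count as one unit); spans are derived at load time.  ``ambiguous`` flags mark
forms whose published label conflicts with the published rules themselves (or
whose letter-level description is bundled by unit-level alignment); they are
excluded from the strict agreement subset.
"""

# id, form, gloss, syllable unit-lengths, stress syllable index, flags
# flags: mw=multiword, vp=verb_past, vi=verb_infinitive, xz=x reads /z/,
#        sr=slot rules ((unit_index, rule_id), ...)
LEXICON_ROWS = [
    (1, "muito", "much", (3, 2), 0, {}),
    (2, "quando", "when", (3, 2), 0, {}),
    (3, "disse", "said", (2, 2), 0, {"sr": ((2, "disse-ss"),)}),
    (4, "também", "also", (3, 3), 1, {}),
    (5, "vez", "time", (3,), 0, {}),
    (6, "cachorro", "dog", (2, 2, 2), 1, {}),
    (7, "conseguiu", "got", (3, 2, 3), 2, {"vp": True}),
    (8, "encontrou", "found", (2, 3, 4), 2, {"vp": True}),
    (9, "gente", "people", (3, 2), 0, {}),
    (10, "guerra", "war", (2, 2), 0, {}),
    (11, "exemplo", "example", (1, 3, 3), 1, {"xz": True}),
    (12, "ajuda", "help", (1, 2, 2), 1, {}),
    (13, "assim", "so", (1, 3), 1, {}),
    (14, "brincar", "play", (4, 3), 1, {"vi": True}),
    (15, "futebol", "soccer", (2, 2, 3), 2, {}),
    (16, "menino", "boy", (2, 2, 2), 1, {}),
    (17, "animal", "animal", (1, 2, 3), 2, {}),
    (18, "carro", "car", (2, 2), 0, {}),
    (19, "casa", "house", (2, 2), 0, {}),
    (20, "então", "then", (2, 3), 1, {}),
    (21, "homem", "man", (2, 3), 0, {}),
    (22, "jeito", "way", (3, 2), 0, {}),
    (23, "por isso", "therefore", (3, 1, 2), 1, {"mw": True}),
    (24, "viajar", "travel", (2, 1, 3), 2, {"vi": True}),
    (25, "a gente", "us", (1, 3, 2), 1, {"mw": True}),
    (26, "almoço", "lunch", (2, 2, 2), 1, {}),
    (27, "assalto", "assault", (1, 3, 2), 1, {}),
    (28, "borracha", "rubber", (2, 2, 2), 1, {}),
    (29, "bruxa", "witch", (3, 2), 0, {}),
    (30, "cabeça", "head", (2, 2, 2), 1, {}),
    (31, "caiu", "fell", (2, 2), 1, {"vp": True}),
    (32, "começou", "started", (2, 2, 3), 2, {"vp": True}),
    (33, "de repente", "suddenly", (2, 2, 3, 2), 2, {"mw": True}),
    (34, "em cima", "above", (2, 2, 2), 1, {"mw": True}),
    (35, "embaixo", "under", (2, 3, 2), 1, {}),
    (36, "enxergar", "see", (2, 3, 3), 2, {"vi": True}),
    (37, "escola", "school", (2, 2, 2), 1, {}),
    (38, "faz", "does", (3,), 0, {}),
    (39, "fazer", "do", (2, 3), 1, {"vi": True}),
    (40, "fez", "did", (3,), 0, {}),
    (41, "girafa", "giraffe", (2, 2, 2), 1, {}),
    (42, "ninguém", "nobody", (3, 3), 1, {}),
    (43, "pegue", "take", (2, 2), 0, {}),
    (44, "porque", "because", (3, 2), 1, {}),
    (45, "professora", "teacher", (3, 2, 2, 2), 2, {}),
    (46, "quente", "hot", (3, 2), 0, {}),
    (47, "tenho", "have", (2, 2), 0, {}),
    (48, "alguém", "somebody", (2, 3), 1, {}),
    (49, "amanhã", "tomorrow", (1, 2, 2), 2, {}),
    (50, "árvore", "tree", (2, 2, 2), 0, {}),
    (51, "certo", "right", (3, 2), 0, {}),
    (52, "correr", "run", (2, 3), 1, {"vi": True}),
    (53, "exame", "test", (1, 2, 2), 1, {"xz": True}),
    (54, "feliz", "happy", (2, 3), 1, {}),
    (55, "presente", "gift", (3, 3, 2), 1, {}),
    (56, "relógio", "clock", (2, 2, 3), 1, {}),
    (57, "saudade", "longing", (3, 2, 2), 1, {}),
    (58, "tempo", "time", (3, 2), 0, {}),
    (59, "tesoura", "scissors", (2, 3, 2), 1, {}),
    (60, "galinha", "chicken", (2, 2, 2), 1, {}),
]

# The published classification table: (word_id, written form, category).
# One row per printed example; the category must be among the predicted
# labels for the pair.
CURATED_EXAMPLE_ROWS = [
    (7, "quancequio", "RPG"),
    (36, "enjeiga", "RPG"),
    (33, "terrepende", "RPG"),
    (7, "cosegiu", "OIL"),
    (27, "alcaldo", "OIL"),
    (35, "ebaixo", "OIL"),
    (27, "alçato", "ASS"),
    (27, "ausato", "ASS"),
    (49, "amahan", "ASS"),
    (35, "em baixo", "USW"),
    (23, "porisso", "USW"),
    (25, "agenti", "IPG_1"),
    (11, "ezenpo", "IPG_1"),
    (36, "emxergar", "IPG_1"),
    (10, "quera", "IPG_1"),
    (53, "isami", "IPG_2"),
    (4, "tabei", "IPG_2"),
    (32, "comessou", "IPG_2"),
    (42, "ningen", "AAW"),
    (50, "arvore", "AAW"),
]

# Per-word analyses: (word_id, form, group, labels, ambiguous, anchor).
# group: "GD", "GWD" or "both".  labels list what the analysis explicitly
# asserts for that form; predictions may be a superset.
GOLD_ROWS = [
    # de repente (33)
    (33, "derepente", "both", ("USW",), False, "joining the preposition"),
    (33, "derrepente", "both", ("USW",), False, "joining the preposition"),
    (33, "terrepende", "GD", ("USW", "RPG"), False, "exchange d/t"),
    (33, "direpente", "GD", ("USW", "RPG"), True, "e->i called RPG"),
    (33, "terepeite", "GD", ("USW", "RPG"), False, "d->t and n->i"),
    # conseguiu (7)
    (7, "quancequio", "GD", ("RPG", "IPG_1"), False, "o->a, gu->qu; c->qu, u->o"),
    (7, "consiquil", "GD", ("RPG", "IPG_1"), True, "pretonic e->i called type 1"),
    (7, "consequil", "GD", ("RPG", "IPG_1"), False, "gu->qu; final u->l"),
    (7, "concequio", "GD", ("RPG", "IPG_1"), False, "gu->qu; final u->o"),
    (7, "cocegir", "GD", ("RPG", "OIL"), False, "u->r; omitting n"),
    (7, "cosegiu", "GD", ("OIL", "IPG_1"), False, "omitting n; gu->g"),
    (7, "cocegiu", "GD", ("OIL", "IPG_1"), False, "omitting n; gu->g"),
    (7, "comseguiu", "GD", ("IPG_1",), False, "n->m"),
    (7, "comsegiu", "GD", ("IPG_1",), False, "n->m, gu->g"),
    (7, "consegil", "GD", ("IPG_1",), False, "gu->g, u->l"),
    (7, "consegio", "GD", ("IPG_1",), False, "gu->g, u->o"),
    (7, "consegiu", "GD", ("IPG_1",), False, "gu->g"),
    (7, "conseguio", "GD", ("IPG_1",), False, "u->o"),
    (7, "conceguio", "GD", ("IPG_1",), False, "u->o"),
    (7, "conseguil", "GD", ("IPG_1",), False, "u->l"),
    # a gente (25)
    (25, "agente", "both", ("USW",), False, "junction of the target word"),
    (25, "aje te", "GD", ("USW", "OIL"), False, "separation; omission of n"),
    (25, "ajeite", "GD", ("RPG", "IPG_2"), False, "n->i; ge/je"),
    (25, "agende", "GD", ("RPG",), False, "t->d"),
    (25, "agenti", "GD", ("IPG_1",), False, "final e->i"),
    (25, "ajente", "GD", ("IPG_2",), False, "ge/je"),
    # por isso (23)
    (23, "porisso", "both", ("USW",), False, "merge"),
    (23, "puriso", "GD", ("RPG", "IPG_2"), True, "o->u called RPG"),
    (23, "porcio", "GD", ("ASS", "IPG_2"), True, "inversion of i and c"),
    (23, "poriço", "GD", ("IPG_2",), False, "ss->ç"),
    (23, "poriso", "GD", ("IPG_2",), False, "ss->s"),
    # ninguém (42)
    (42, "ningen", "GD", ("AAW", "IPG_1", "IPG_2"), False, "gu->g; final n"),
    (42, "nigei", "GD", ("IPG_2", "IPG_1", "OIL"), False, "omission; gu->g; final"),
    (42, "mingen", "GD", ("IPG_1", "IPG_2"), False, "gu->g; final n"),
    (42, "ningem", "GD", ("IPG_1", "AAW"), False, "gu->g; accent"),
    (42, "niguem", "GD", ("OIL", "AAW"), False, "omission of nasalization"),
    (42, "ningue", "GD", ("OIL", "AAW"), False, "omission of final m"),
    (42, "ninque", "GD", ("OIL", "RPG", "AAW"), False, "g->q; omission"),
    (42, "mimguem", "GD", ("RPG", "AAW"), False, "m for n"),
    # assalto (27)
    (27, "asalto", "both", ("IPG_2",), False, "ss->s"),
    (27, "asauto", "both", ("IPG_2",), False, "ss->s, l->u"),
    (27, "açalto", "GD", ("IPG_2",), False, "ss->ç"),
    (27, "auçato", "GD", ("IPG_2", "ASS"), False, "semivowel moved"),
    (27, "ausato", "GD", ("IPG_2", "ASS"), False, "semivowel moved"),
    (27, "alçato", "GD", ("IPG_2", "ASS"), False, "semivowel moved"),
    (27, "assauto", "GD", ("IPG_2",), False, "l->u"),
    (27, "acauto", "GD", ("IPG_2", "RPG"), False, "ss->c; l->u"),
    (27, "assatou", "GD", ("ASS",), False, "semivowel to last syllable"),
    (27, "alcaldo", "GD", ("OIL", "RPG"), False, "addition of l; ss->c, t->d"),
    # alguém (48)
    (48, "alguem", "GWD", ("AAW",), False, "absence of accent"),
    (48, "algem", "GD", ("IPG_1", "AAW"), False, "digraph not preserved"),
    (48, "augen", "GD", ("IPG_1", "IPG_2", "AAW"), False, "digraph; u; final n"),
    (48, "amgen", "GD", ("IPG_1", "IPG_2", "RPG", "AAW"), False, "l->m"),
    (48, "alqen", "GD", ("IPG_2", "RPG", "AAW"), False, "gu->q"),
    (48, "alquém", "GD", ("RPG",), False, "g->que"),
    # exame (53)
    (53, "ezaime", "GD", ("OIL", "IPG_1"), False, "addition of i; x->z"),
    (53, "exaime", "GD", ("OIL",), False, "addition of i"),
    (53, "ezami", "GD", ("IPG_1",), False, "x->z, e->i"),
    (53, "esami", "GD", ("IPG_1",), False, "x->s, e->i"),
    (53, "esame", "GD", ("IPG_1",), False, "x->s"),
    (53, "isami", "GD", ("IPG_2",), False, "initial e->i"),
    (53, "exami", "GWD", ("IPG_1",), False, "final e->i"),
    # faz / fez (38 / 40)
    (38, "fais", "GD", ("IPG_2", "OIL"), False, "z->s; addition of i"),
    (38, "fas", "GD", ("IPG_2",), False, "z->s"),
    (40, "feis", "GD", ("IPG_2", "OIL"), False, "z->s; addition of i"),
    (40, "feize", "GD", ("OIL",), False, "addition"),
    (40, "feiz", "GD", ("OIL",), False, "addition of i"),
    # em cima (34)
    (34, "ensima", "GD", ("USW", "IPG_1", "IPG_2"), False, "m->n; c->s"),
    (34, "emcima", "GD", ("USW",), False, "junction"),
    (34, "incima", "GD", ("USW", "IPG_1"), True, "in- called type 1"),
    (34, "enssima", "GD", ("USW", "IPG_1", "IPG_2"), False, "m->n; c->ss"),
    (34, "encina", "GD", ("USW", "IPG_1", "RPG"), False, "m->n onset"),
    (34, "emicima", "GD", ("USW", "OIL"), False, "addition of i"),
    (34, "emsima", "GWD", ("USW", "IPG_2"), False, "c->s"),
    # embaixo (35)
    (35, "em baixo", "GWD", ("USW",), False, "hypersegmentation"),
    (35, "em baicho", "GD", ("USW", "IPG_1"), False, "split; x->ch"),
    (35, "embaiso", "GD", ("RPG",), False, "x->s"),
    (35, "embaijo", "GD", ("RPG",), False, "x->j"),
    (35, "enbaço", "GD", ("RPG", "OIL", "IPG_1"), False, "x->ç; omit i; m->n"),
    (35, "ebaixo", "GD", ("OIL",), False, "omission of m"),
    (35, "embaicho", "GD", ("IPG_1",), False, "x->ch after diphthong"),
    (35, "enbaichu", "GD", ("IPG_1",), False, "m->n, x->ch, o->u"),
    # também (4)
    (4, "tambem", "both", ("AAW",), False, "without the acute accent"),
    (4, "tabei", "GD", ("IPG_2", "OIL", "AAW"), False, "final; omit m"),
    (4, "tanbei", "GD", ("IPG_2", "IPG_1", "AAW"), False, "m->n; final"),
    (4, "tanbe", "GD", ("IPG_1", "OIL", "AAW"), False, "m->n; omit m"),
    (4, "tanpem", "GD", ("IPG_1", "RPG", "AAW"), False, "m->n; b->p"),
    (4, "tanbem", "GD", ("IPG_1", "AAW"), False, "m->n"),
    (4, "dampem", "GD", ("RPG", "AAW"), False, "t->d, b->p"),
    (4, "tabem", "GD", ("OIL", "AAW"), False, "omit m"),
    (4, "tabe", "GD", ("OIL", "AAW"), False, "omit m twice"),
    # exemplo (11)
    (11, "esenplo", "GD", ("IPG_1",), False, "x->s; m->n"),
    (11, "esenplu", "GD", ("IPG_1",), False, "x->s; m->n; o->u"),
    (11, "eseplo", "GD", ("IPG_1", "OIL"), False, "x->s; omit m"),
    (11, "esemplo", "GD", ("IPG_1",), False, "x->s"),
    (11, "ezenplu", "GD", ("IPG_1",), False, "x->z; m->n; o->u"),
    (11, "ezenplo", "GD", ("IPG_1",), False, "x->z; m->n"),
    (11, "ezenpo", "GD", ("IPG_1", "OIL"), False, "x->z; m->n; omit l"),
    (11, "ezeblo", "GD", ("RPG", "OIL", "IPG_1"), False, "p->b; omit m; x->z"),
    (11, "ezemplo", "GD", ("IPG_1",), False, "x->z"),
    (11, "egenpo", "GD", ("RPG", "OIL"), False, "x->g; omit l"),
    (11, "exenplo", "GWD", ("IPG_1",), False, "m->n"),
    (11, "exmplo", "GD", ("OIL",), False, "omission"),
    (11, "exsemplo", "GD", ("OIL",), True, "addition bundled by xs digraph"),
    (11, "enxemplo", "GD", ("OIL",), False, "addition of n"),
    # enxergar (36)
    (36, "emxergar", "both", ("IPG_1",), False, "n->m"),
    (36, "enchergar", "both", ("IPG_1",), False, "x->ch after en"),
    (36, "enchega", "GD", ("IPG_1", "OIL"), False, "x->ch; omit r"),
    (36, "enjergar", "GWD", ("RPG",), False, "x->j"),
    (36, "enjeiga", "GD", ("RPG", "OIL"), False, "x->j; add i; omit r"),
    (36, "enserga", "GD", ("RPG", "OIL"), False, "x->s; omit r"),
    (36, "ençega", "GD", ("RPG", "OIL"), False, "x->ç; omit r"),
    # guerra (10)
    (10, "querra", "GD", ("RPG",), False, "gu->qu"),
    (10, "quera", "GD", ("RPG", "IPG_1"), False, "gu->qu; rr->r"),
    (10, "guera", "GD", ("IPG_1",), False, "rr->r"),
    (10, "gera", "GD", ("IPG_1",), False, "gu->g; rr->r"),
    (10, "gerra", "GD", ("IPG_1",), False, "gu->g"),
    # caiu (31)
    (31, "caio", "GD", ("IPG_1",), False, "u->o in simple past"),
    (31, "caío", "GD", ("IPG_1", "AAW"), False, "u->o; accent"),
    # começou (32)
    (32, "comesou", "both", ("IPG_2",), False, "ç->s"),
    (32, "comessou", "GD", ("IPG_2",), False, "ç->ss"),
    (32, "comesol", "GD", ("IPG_2", "IPG_1"), False, "ç->s; u->l"),
    (32, "comeisou", "GD", ("IPG_2", "OIL"), False, "ç->s; insertion"),
    (32, "comeco", "GD", ("RPG", "OIL"), False, "without cedilla; omit u"),
    (32, "comecou", "GD", ("RPG",), False, "without cedilla"),
    # vez (5)
    (5, "fez", "GD", ("RPG",), False, "v->f"),
    (5, "veiz", "GD", ("OIL",), False, "adding i"),
    (5, "veis", "GD", ("OIL", "IPG_2"), False, "adding i; z->s"),
    (5, "ves", "GD", ("IPG_2",), False, "z->s"),
    # relógio (56)
    (56, "relogio", "GWD", ("AAW",), False, "absence of accent"),
    (56, "relojo", "GD", ("IPG_2", "OIL", "AAW"), False, "g->j; omit i"),
    (56, "relozo", "GD", ("RPG", "OIL", "AAW"), False, "g->z; omit i"),
    # jeito (22)
    (22, "geito", "both", ("IPG_2",), False, "j->g"),
    (22, "geitu", "GD", ("IPG_2", "IPG_1"), False, "j->g; o->u"),
    (22, "jento", "GD", ("RPG",), False, "i->n"),
    (22, "jeto", "GD", ("OIL",), False, "omit i"),
    # disse (3)
    (3, "dice", "GD", ("IPG_1",), False, "morphological ss"),
    (3, "dici", "GD", ("IPG_1",), False, "morphological ss; e->i"),
    (3, "dise", "GD", ("IPG_1",), False, "morphological ss"),
    (3, "diçe", "GD", ("IPG_1",), False, "morphological ss"),
    # árvore (50)
    (50, "arvore", "both", ("AAW",), False, "absence of accent"),
    (50, "avori", "GD", ("AAW", "OIL", "IPG_2"), False, "accent; omit r; e->i"),
    (50, "arvoré", "GD", ("AAW",), False, "misplaced accent"),
    (50, "ávore", "GD", ("OIL",), False, "omit r"),
    # saudade (57)
    (57, "saldade", "both", ("IPG_1",), True, "u->l called type 1"),
    (57, "saltade", "GD", ("IPG_1", "RPG"), True, "u->l; d->t"),
    (57, "çaudade", "GD", ("IPG_1",), True, "initial ç called type 1"),
    (57, "caudade", "GD", ("RPG",), False, "s->c"),
    # pegue (43)
    (43, "pege", "both", ("IPG_1",), False, "gu->g"),
    (43, "pegi", "GD", ("IPG_1",), False, "gu->g; e->i"),
    (43, "pegui", "GD", ("IPG_1",), False, "e->i"),
    (43, "peque", "GD", ("RPG",), False, "g->q in the digraph"),
    # borracha (28)
    (28, "borraja", "GD", ("RPG",), False, "ch->j"),
    (28, "boraja", "GD", ("RPG", "IPG_1"), False, "ch->j; rr->r"),
    (28, "borasa", "GD", ("RPG", "IPG_1"), False, "ch->s; rr->r"),
    (28, "boraija", "GD", ("RPG", "OIL", "IPG_1"), False, "add i"),
    (28, "boraxa", "GD", ("IPG_1", "IPG_2"), False, "rr->r; ch->x"),
    (28, "borraxa", "GD", ("IPG_2",), False, "ch->x"),
    (28, "boracha", "both", ("IPG_1",), False, "rr->r"),
    # assim (13)
    (13, "aci", "GD", ("IPG_2", "OIL"), False, "ss->c; omit m"),
    (13, "assi", "GD", ("OIL",), False, "omit m"),
    (13, "acim", "GD", ("IPG_2",), False, "ss->c"),
    (13, "asim", "GD", ("IPG_2",), False, "ss->s"),
    (13, "assin", "GWD", ("IPG_1",), True, "final n called type 1"),
    # amanhã (49)
    (49, "amanha", "both", ("IPG_1",), False, "absence of the tilde"),
    (49, "amanham", "GD", ("IPG_1",), False, "tilde; final m"),
    (49, "amahan", "GD", ("IPG_1", "ASS"), False, "syllable restructuring"),
    # correr (52)
    (52, "corre", "both", ("OIL",), False, "omit final r"),
    (52, "corer", "GD", ("IPG_1",), False, "rr->r"),
    # homem (21)
    (21, "homen", "both", ("IPG_2",), False, "n instead of m"),
    (21, "homin", "GD", ("IPG_2", "RPG"), False, "final n; e->i"),
    (21, "homei", "GD", ("IPG_2",), False, "final"),
    (21, "omen", "GD", ("IPG_2",), False, "omit h; final n"),
    (21, "omei", "GD", ("IPG_2",), False, "omit h"),
    (21, "omem", "GD", ("IPG_2",), False, "omit h"),
    (21, "home", "GD", ("OIL",), False, "omit final m"),
    # brincar (14)
    (14, "brica", "GD", ("OIL",), False, "omissions"),
    (14, "bincar", "GD", ("OIL",), False, "omit r"),
    (14, "binca", "GD", ("OIL",), False, "omissions"),
    (14, "bicar", "GD", ("OIL",), False, "omissions"),
    (14, "brinca", "GD", ("OIL",), False, "omit final r"),
    (14, "princar", "GD", ("RPG",), False, "b->p"),
    # gente (9)
    (9, "jende", "GD", ("RPG", "IPG_2"), False, "t->d; g->j"),
    (9, "jete", "GD", ("OIL", "IPG_2"), False, "omit n; g->j"),
    (9, "jeti", "GD", ("OIL", "IPG_2", "IPG_1"), False, "omit n; e->i"),
    (9, "genti", "GD", ("IPG_1",), False, "final e->i"),
    (9, "jente", "GD", ("IPG_2",), False, "g->j"),
    # viajar (24)
    (24, "viaja", "both", ("OIL",), False, "omit final r"),
    (24, "viagar", "GD", ("IPG_1",), False, "j->g"),
    # certo (51)
    (51, "serto", "GD", ("IPG_2",), False, "c->s"),
    (51, "sertu", "GD", ("IPG_2", "IPG_1"), False, "c->s; o->u"),
    # encontrou (8)
    (8, "emcontrou", "GD", ("IPG_1",), False, "n->m"),
    (8, "encomtrou", "GD", ("IPG_1",), False, "n->m"),
    (8, "encomtrol", "GD", ("IPG_1",), False, "n->m; u->l"),
    (8, "emcomtrol", "GD", ("IPG_1",), False, "n->m; u->l"),
    (8, "encontrol", "GD", ("IPG_1",), False, "u->l"),
    (8, "incontrol", "GD", ("IPG_1", "IPG_2"), False, "u->l; pretonic e->i"),
    (8, "incontrou", "GD", ("IPG_2",), False, "pretonic e->i"),
    (8, "encontro", "GD", ("OIL",), False, "omit u"),
    (8, "encontor", "GD", ("OIL", "ASS"), False, "tor for trou"),
    # quente (46)
    (46, "qenti", "GD", ("IPG_1",), False, "qu->q; e->i"),
    (46, "qente", "GD", ("IPG_1",), False, "qu->q"),
    (46, "quenti", "GD", ("IPG_1",), False, "e->i"),
    (46, "queinte", "GD", ("OIL",), False, "add i"),
    (46, "guente", "GWD", ("RPG",), False, "q->g in the digraph"),
    # futebol (15)
    (15, "fotebol", "both", ("IPG_2",), False, "pretonic u->o"),
    (15, "futibol", "GD", ("IPG_2",), False, "pretonic e->i"),
    (15, "futibou", "GD", ("IPG_2",), False, "e->i; l->u"),
    (15, "futebou", "GD", ("IPG_2",), False, "final l->u"),
    (15, "fultebol", "both", ("OIL",), False, "addition of l"),
    (15, "futeboll", "GD", ("OIL",), False, "addition of l"),
    (15, "futball", "GWD", ("OTHER",), False, "English influence"),
    # tenho (47)
    (47, "tenhor", "GWD", ("OIL",), False, "addition of r"),
    (47, "teinho", "GD", ("OIL",), False, "addition of i"),
    (47, "teo", "GD", ("OIL",), False, "omission of nh"),
    (47, "temum", "GD", ("OTHER",), False, "classified as others"),
    (47, "teiu", "GD", ("RPG", "IPG_1"), False, "nh->i; u for o"),
    # tempo (58)
    (58, "tenpo", "both", ("IPG_1",), False, "m before p/b"),
    (58, "tenpu", "GD", ("IPG_1",), False, "m->n; o->u"),
    (58, "tepo", "GD", ("OIL",), False, "omit m"),
    # tesoura (59)
    (59, "dezora", "GD", ("RPG", "OIL", "IPG_2"), False, "t->d; omit u; s->z"),
    (59, "tezoura", "GD", ("IPG_2",), False, "s->z"),
    # fazer (39)
    (39, "vazer", "GD", ("RPG",), False, "f->v"),
    (39, "faser", "GD", ("IPG_2",), False, "z->s intervocalic"),
    # ajuda (12)
    (12, "aguda", "GD", ("IPG_1",), False, "j->g"),
    (12, "axuda", "GD", ("RPG",), False, "j->x"),
    (12, "ajudar", "GD", ("OIL",), False, "addition of final r"),
    # muito (1)
    (1, "muinto", "both", ("OIL",), False, "addition of n"),
    (1, "munito", "GD", ("OIL",), False, "addition of n"),
    (1, "muitu", "GD", ("IPG_1",), False, "o->u"),
    # então (20)
    (20, "emtão", "GWD", ("IPG_1",), False, "n->m before t"),
    (20, "entam", "GD", ("IPG_1",), False, "spelling of [ãw]"),
    (20, "intau", "GD", ("IPG_1", "IPG_2"), False, "tilde; pretonic e->i"),
    (20, "eitão", "GD", ("RPG",), False, "i instead of n"),
    # quando (2)
    (2, "guando", "GD", ("RPG",), False, "q->g"),
    (2, "gando", "GD", ("RPG", "OIL"), True, "letter-level omission bundled"),
    (2, "cando", "GD", ("RPG",), True, "word-level sound change"),
    (2, "cuado", "GD", ("OIL", "IPG_2"), True, "qu/cu irregularity"),
    (2, "quamdo", "GD", ("IPG_1",), False, "n->m"),
    # cachorro (6)
    (6, "cachoro", "GD", ("IPG_1",), False, "rr->r"),
    (6, "caxoro", "GD", ("IPG_1", "IPG_2"), False, "rr->r; ch->x"),
    (6, "caxorro", "GD", ("IPG_2",), False, "ch->x"),
    # presente (55)
    (55, "prezenti", "GD", ("IPG_1", "IPG_2"), False, "s->z; e->i"),
    (55, "prezente", "GD", ("IPG_2",), False, "s->z"),
    (55, "prezete", "GD", ("IPG_2", "OIL"), False, "s->z; omit n"),
    # bruxa (29)
    (29, "bruça", "GD", ("RPG",), False, "x->ç"),
    (29, "bruja", "GD", ("RPG",), False, "x->j"),
    (29, "bruija", "GD", ("RPG", "OIL"), False, "x->j; add i"),
    (29, "brucha", "GD", ("IPG_2",), False, "x->ch"),
    # animal (17)
    (17, "animao", "GD", ("IPG_2",), False, "final l->o"),
    (17, "animau", "GD", ("IPG_2",), False, "final l->u"),
    # girafa (41)
    (41, "jirafa", "GD", ("IPG_2",), False, "g->j"),
    (41, "girrafa", "GD", ("IPG_1",), False, "r->rr"),
    # carro (18)
    (18, "caro", "GD", ("IPG_1",), False, "rr->r"),
    # galinha (60)
    (60, "galilha", "GD", ("RPG",), False, "nh->lh"),
    # porque (44)
    (44, "poorgue", "GD", ("RPG", "OIL"), False, "qu->gu; add o"),
    (44, "poque", "GD", ("OIL",), False, "omit r"),
    (44, "proque", "GD", ("ASS",), False, "order of the graphemes"),
    # menino (16)
    (16, "minino", "GD", ("IPG_2",), False, "pretonic e->i"),
    # cabeça (30)
    (30, "cabesa", "GD", ("IPG_2",), False, "ç->s"),
    (30, "cabessa", "GD", ("IPG_2",), False, "ç->ss"),
    (30, "cabeca", "GD", ("RPG",), False, "without cedilla"),
    # professora (45)
    (45, "profesora", "GD", ("IPG_2",), False, "ss->s"),
    # almoço (26)
    (26, "almoso", "both", ("IPG_2",), False, "ç->s"),
    (26, "almouso", "GD", ("IPG_2", "OIL"), False, "ç->s; add u"),
    (26, "aumoso", "GD", ("IPG_2",), False, "l->u; ç->s"),
    (26, "aumoço", "GD", ("IPG_2",), False, "l->u"),
    (26, "au moço", "GD", ("IPG_2", "USW"), False, "split variant"),
    (26, "almoção", "GD", ("OTHER",), False, "classified as others"),
    # feliz (54)
    (54, "felis", "GD", ("IPG_2",), False, "z->s"),
]

# Correct/incorrect counts per word and group (30 students per group).
# (word_id, GD correct, GD incorrect, GWD correct, GWD incorrect, printed p)
# Note: the published GWD percentage for word 3 reads "933%", an obvious
# misprint of 93.3%; counts are stored as printed (28 correct, 2 incorrect).
WORD_COUNT_ROWS = [
    (1, 23, 7, 29, 1, "0.052"),
    (2, 24, 6, 30, 0, "0.024"),
    (3, 13, 17, 28, 2, "<0.001"),
    (4, 8, 22, 25, 5, "<0.001"),
    (5, 11, 19, 30, 0, "<0.001"),
    (6, 24, 6, 30, 0, "0.024"),
    (7, 2, 28, 19, 11, "<0.001"),
    (8, 19, 11, 30, 0, "<0.001"),
    (9, 18, 12, 30, 0, "<0.001"),
    (10, 9, 21, 29, 1, "<0.001"),
    (11, 9, 21, 28, 2, "<0.001"),
    (12, 22, 8, 30, 0, "0.005"),
    (13, 15, 15, 29, 1, "<0.001"),
    (14, 17, 13, 30, 0, "<0.001"),
    (15, 21, 9, 27, 3, "0.053"),
    (16, 29, 1, 30, 0, "1.000"),
    (17, 26, 4, 30, 0, "0.112"),
    (18, 27, 3, 30, 0, "0.237"),
    (19, 30, 0, 30, 0, None),
    (20, 24, 6, 28, 2, "0.254"),
    (21, 17, 13, 29, 1, "<0.001"),
    (22, 12, 18, 29, 1, "<0.001"),
    (23, 3, 27, 24, 6, "<0.001"),
    (24, 18, 12, 29, 1, "0.001"),
    (25, 2, 28, 20, 10, "<0.001"),
    (26, 10, 20, 28, 2, "<0.001"),
    (27, 4, 26, 24, 6, "<0.001"),
    (28, 14, 16, 29, 1, "<0.001"),
    (29, 25, 5, 30, 0, "0.052"),
    (30, 20, 10, 30, 0, "0.001"),
    (31, 9, 21, 30, 0, "<0.001"),
    (32, 10, 20, 29, 1, "<0.001"),
    (33, 1, 29, 21, 9, "<0.001"),
    (34, 8, 22, 24, 6, "<0.001"),
    (35, 7, 23, 24, 6, "<0.001"),
    (36, 9, 21, 24, 6, "<0.001"),
    (37, 30, 0, 30, 0, None),
    (38, 8, 22, 29, 1, "<0.001"),
    (39, 22, 8, 30, 0, "0.005"),
    (40, 7, 23, 29, 1, "<0.001"),
    (41, 26, 4, 30, 0, "0.112"),
    (42, 3, 27, 20, 10, "<0.001"),
    (43, 14, 16, 29, 1, "<0.001"),
    (44, 27, 3, 30, 0, "0.237"),
    (45, 20, 10, 30, 0, "0.001"),
    (46, 19, 11, 29, 1, "0.001"),
    (47, 22, 8, 29, 1, "0.026"),
    (48, 4, 26, 25, 5, "<0.001"),
    (49, 15, 15, 27, 3, "0.001"),
    (50, 13, 17, 28, 2, "<0.001"),
    (51, 18, 12, 30, 0, "<0.001"),
    (52, 16, 14, 27, 3, "0.002"),
    (53, 6, 24, 26, 4, "<0.001"),
    (54, 21, 9, 30, 0, "0.002"),
    (55, 24, 6, 30, 0, "0.024"),
    (56, 11, 19, 24, 6, "0.001"),
    (57, 14, 16, 27, 3, "<0.001"),
    (58, 22, 8, 27, 3, "0.095"),
    (59, 22, 8, 30, 0, "0.005"),
    (60, 27, 3, 30, 0, "0.237"),
]

# Per-grade incorrect-word totals: (grade, group, n_students, total_incorrect)
GRADE_TOTALS = [
    (3, "GD", 10, 387),
    (3, "GWD", 10, 62),
    (4, "GD", 8, 236),
    (4, "GWD", 8, 37),
    (5, "GD", 4, 93),
    (5, "GWD", 4, 19),
    (6, "GD", 8, 133),
    (6, "GWD", 8, 10),
]

# Distinct-error-form counts per group and category (the study's category
# breakdown of the 399 GD / 51 GWD distinct incorrect forms).  AAW and USW
# entries are the class remainders (228-124-91 and 171-80-60-7 for GD;
# 33-17-12 and 18-7-4-0 for GWD).  OTHER forms fall outside those class
# totals: the printed GD other-forms are two; GWD had one occurrence.
DISTINCT_FORM_COUNTS = {
    "GD": {"IPG_1": 124, "IPG_2": 91, "AAW": 13,
           "OIL": 80, "RPG": 60, "USW": 24, "ASS": 7, "OTHER": 2},
    "GWD": {"IPG_1": 17, "IPG_2": 12, "AAW": 4,
            "OIL": 7, "USW": 7, "RPG": 4, "ASS": 0, "OTHER": 1},
}

# Group sizes per grade (same for GD and GWD)
GROUP_SIZES = {3: 10, 4: 8, 5: 4, 6: 8}

# Overall means of incorrectly written words (out of 60) and their printed
# percentages (truncated to 2 d.p., see analysis.truncate_pct).
GROUP_MEANS = {"GD": 28.3, "GWD": 4.3}
GROUP_MEAN_PCT = {"GD": 47.16, "GWD": 7.16}
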
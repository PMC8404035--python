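import pytest

from ontomine.corpus import Corpus, Post, Thread
from ontomine.ontology import Ontology, OntologyClass, SynonymAnnotation
from ontomine.textprep import load_stopwords


def make_post(post_id, thread_id, forum_id, position, text):
    return Post(post_id=post_id, thread_id=thread_id, forum_id=forum_id,
                position=position, text=text)


def make_corpus(spec):
    """Build a corpus from {forum_id: [[post texts per thread], ...]}."""
    threads = []
    counter = 0
    for forum_id, thread_texts in spec.items():
        for t_idx, texts in enumerate(thread_texts):
            tid = f"{forum_id}-t{t_idx}"
            posts = []
            for pos, text in enumerate(texts):
                posts.append(make_post(f"p{counter}", tid, forum_id, pos, text))
                counter += 1
            threads.append(Thread(thread_id=tid, forum_id=forum_id, posts=tuple(posts)))
    return Corpus(threads=tuple(threads))


@pytest.fixture(scope="session")
def stopwords():
    return load_stopwords()


@pytest.fixture()
def toy_ontology():
    classes = {
        "OCIMIDO:00141": OntologyClass(
            id="OCIMIDO:00141",
            label="blurred vision",
            synonyms=(SynonymAnnotation("blurry", "OV", "unspecified"),),
            xrefs=("SNOMEDCT:246636008",),
        ),
        "OCIMIDO:00213": OntologyClass(
            id="OCIMIDO:00213",
            label="uveitis",
            parents=("OCIMIDO:00141",),  # structural toy, not clinical truth
        ),
        "OCIMIDO:00302": OntologyClass(
            id="OCIMIDO:00302",
            label="adalimumab",
            relationships=(("RO:0002606", "OCIMIDO:00213"),),
        ),
    }
    return Ontology(classes=classes, relation_types={"RO:0002606": "treatment of"},
                    name="toy")
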
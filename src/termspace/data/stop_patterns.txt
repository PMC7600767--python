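# Function words, auxiliaries and generic adverbs whose pairing with a key
# term is a window artifact ("also predicted", "can be predicted"), not a
# collocation.  One lowercase token per line; '#' starts a comment.
# auxiliaries / copulas
am
are
be
been
being
can
could
did
do
does
had
has
have
is
may
might
must
shall
should
was
were
will
would
# generic adverbs / participial connectives
also
based
highly
however
more
most
often
only
toward
towards
using
used
very
# determiners
a
an
any
each
no
some
that
the
these
this
those
# prepositions / conjunctions / pronouns
and
as
at
but
by
for
from
in
into
it
its
not
of
on
or
our
than
their
them
they
to
we
which
with
within
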
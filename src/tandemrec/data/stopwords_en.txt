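# minimal English stop-word list for description tagging
a
an
and
are
as
at
be
but
by
for
from
has
have
he
her
his
i
in
is
it
its
of
on
or
she
that
the
their
them
they
this
to
was
we
were
with
you
your
about
after
all
also
before
during
into
our
over
some
then
there
when
which
while
who
will
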
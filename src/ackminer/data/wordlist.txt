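a
able
about
above
academic
accept
access
according
account
achieve
acid
acknowledge
acknowledged
acknowledgement
acknowledgements
acknowledgment
acknowledgments
across
act
active
activity
add
addition
additional
advance
advice
affiliation
after
again
against
age
agency
ago
agree
agreement
aid
all
allow
almost
alone
along
already
also
although
always
am
among
amount
an
analyses
analysis
and
animal
animals
another
answer
anti
antibodies
antibody
antigen
any
anyone
anything
appear
apply
approach
appreciate
appreciation
are
area
argue
arise
arm
around
as
ask
assay
assays
assistance
assume
at
attention
author
authors
autoimmune
available
award
away
back
bank
base
based
be
became
because
become
been
before
began
begin
behind
being
believe
below
best
better
between
beyond
big
bind
binding
biology
blood
board
body
bone
both
brain
bring
brought
build
but
buy
by
call
called
came
can
cannot
care
careful
carefully
carry
case
cases
cell
cells
center
centre
central
certain
chain
chance
change
chapter
character
charge
check
chemical
child
children
choice
choose
city
claim
class
clear
clearly
clinical
clone
clones
close
cocktail
cocktails
code
cold
colleague
colleagues
collect
collection
college
come
comment
comments
committee
common
community
company
compare
complete
complex
compound
compounds
concentration
condition
conditions
conduct
confirm
consider
constant
construct
constructs
contain
continue
contribute
contribution
contributions
control
controls
core
cost
could
council
count
country
course
create
critical
critically
cross
culture
cultures
current
cut
cytometry
data
day
deal
dear
death
debt
decide
deep
degree
department
depend
describe
design
despite
detail
develop
development
did
die
difference
different
difficult
direct
direction
director
discuss
discussion
discussions
disease
distribution
division
do
doctor
does
donate
donated
donating
donation
donations
done
donor
donors
down
draft
draw
drive
drop
drug
drugs
during
each
early
earlier
easy
edit
editing
editorial
education
effect
effective
effort
efforts
eight
either
electron
else
embryo
embryos
emphasis
end
energy
enough
ensure
entire
environment
enzyme
enzymes
especially
establish
even
event
ever
every
everyone
everything
evidence
exact
examine
example
excellent
except
exchange
expect
experiment
experimental
experiments
expert
expertise
explain
express
expression
extend
extra
extract
extraction
eye
face
facility
fact
factor
faculty
fail
fall
family
far
fee
feel
fellow
fellowship
fellowships
few
field
figure
figures
final
financial
find
finding
fine
first
fish
five
flies
flow
fluorescence
fly
focus
follow
following
food
for
force
form
former
forward
found
foundation
four
free
friend
from
front
full
function
fund
funded
funding
funds
further
future
gave
gene
general
generate
generated
generous
generously
genes
genetic
genome
get
gift
gifts
give
given
giving
go
good
got
government
graduate
grant
grants
grateful
gratefully
great
greatly
ground
group
groups
grow
growth
guidance
had
hand
happen
hard
has
have
he
head
health
hear
heart
held
help
helped
helpful
her
here
herself
high
him
himself
his
history
hold
home
hospital
host
hour
house
how
however
human
hybridoma
idea
identify
if
image
images
imaging
immune
important
improve
in
include
included
including
increase
indeed
individual
individuals
information
initial
input
insect
insects
insight
insightful
insights
institute
institution
instrument
instruments
interest
interesting
international
into
invaluable
investigator
investigators
involve
is
issue
it
item
its
itself
job
join
journal
just
keep
kind
kindly
know
knowledge
known
lab
laboratories
laboratory
large
last
late
later
lead
learn
least
leave
led
left
less
let
letter
level
library
life
light
like
likely
limit
line
lines
list
little
live
local
long
look
lot
low
machine
made
main
maintain
major
make
making
man
manage
management
manner
manuscript
manuscripts
many
mass
material
materials
matter
may
me
mean
means
measure
measurement
medical
medicine
meet
meeting
member
members
membrane
memorial
mention
method
methods
mice
microscope
microscopy
might
mind
ministry
minute
model
models
molecular
molecule
molecules
moment
money
monoclonal
month
more
most
mouse
move
much
must
my
name
national
natural
nature
near
nearly
necessary
need
network
never
new
next
nice
no
none
nor
normal
not
note
nothing
now
nuclear
number
numerous
observation
observations
obtain
obtained
of
off
offer
office
often
old
on
once
one
ongoing
only
onto
open
operation
opinion
opportunity
or
order
organization
original
other
others
our
out
outside
over
own
page
paper
papers
parent
part
partial
partially
participants
particular
particularly
partly
past
patient
patients
pattern
pay
people
per
percent
performance
performed
perhaps
period
person
personal
personnel
phase
picture
piece
place
plan
plant
plants
plasma
plasmid
plasmids
platform
play
please
point
policy
polyclonal
poor
population
position
possible
power
practice
preparation
prepare
present
president
press
previous
primary
principal
prior
probe
probes
problem
process
produce
product
professor
program
programme
project
projects
promote
proposal
protein
proteins
protocol
protocols
prove
provide
provided
providing
public
publication
publish
published
purchase
purpose
put
quality
question
questions
quite
raise
raised
ran
range
rat
rate
rather
rats
reach
read
reading
reagent
reagents
real
really
reason
receive
received
recent
recombinant
record
red
reference
region
related
remain
remember
report
request
require
research
researcher
researchers
resource
resources
respect
response
rest
result
results
return
review
reviewer
reviewers
right
rise
role
room
run
said
same
sample
samples
save
saw
say
scheme
scholar
scholarship
school
science
sciences
scientific
scientist
scientists
screen
second
secondary
section
sections
secretarial
see
seem
seen
self
send
senior
sense
sequence
sequences
sequencing
series
serum
serve
service
services
set
seven
several
shall
share
sharing
she
short
should
show
shown
side
significant
similar
simple
since
single
site
situation
six
size
skill
skillful
small
so
social
society
some
someone
something
sometimes
son
soon
sort
source
sources
space
speak
special
specific
spend
staff
stage
stain
staining
stand
standard
start
state
statistical
stay
step
still
stimulating
stock
stocks
stop
strain
strains
strong
structure
student
students
studies
study
sub
subject
substrate
success
successful
such
suggest
suggestion
suggestions
summer
superb
supervision
supply
support
supported
supporting
sure
surface
synthesis
system
table
take
taken
talk
team
technical
technique
techniques
technology
tell
ten
term
test
tested
tests
text
than
thank
thanked
thankful
thanks
that
the
their
them
themselves
then
theory
there
therefore
these
they
thing
think
third
this
those
though
thought
three
through
throughout
thus
time
tissue
tissues
to
today
together
too
took
tool
tools
top
total
toward
towards
training
transfer
transgenic
travel
trial
true
trust
try
turn
two
type
types
under
understand
understanding
unit
university
unknown
until
up
upon
us
use
used
useful
using
usually
valuable
value
variety
various
vector
vectors
very
via
view
virus
viruses
visit
vital
want
was
water
way
ways
we
week
welfare
well
went
were
what
when
where
whether
which
while
who
whole
whom
whose
why
wide
will
wish
with
within
without
woman
word
work
works
workshop
world
would
write
writing
written
wrote
year
years
yeast
yet
you
young
your
we'd
we're
it's
don't
can't
author's
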
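the
be
to
of
and
a
in
that
have
i
it
for
not
on
with
he
as
you
do
at
this
but
his
by
from
they
we
say
her
she
or
an
will
my
one
all
would
there
their
what
so
up
out
if
about
who
get
which
go
me
when
make
can
like
time
no
just
him
know
take
people
into
year
your
good
some
could
them
see
other
than
then
now
look
only
come
its
over
think
also
back
after
use
two
how
our
work
first
well
way
even
new
want
because
any
these
give
day
most
us
is
was
are
were
been
has
had
did
said
doing
am
being
goes
gone
made
knew
thought
looked
wanted
gave
used
found
told
asked
seemed
felt
left
put
meant
kept
let
began
seem
help
talk
turn
start
might
show
hear
play
run
move
live
believe
hold
bring
happen
write
provide
sit
stand
lose
pay
meet
include
continue
set
learn
change
lead
understand
watch
follow
stop
create
speak
read
allow
add
spend
grow
open
walk
win
offer
remember
love
consider
appear
buy
wait
serve
die
send
expect
build
stay
fall
cut
reach
kill
remain
suggest
raise
pass
sell
require
report
decide
pull
home
water
room
mother
area
money
story
fact
month
lot
right
study
book
eye
job
word
business
issue
side
kind
head
house
service
friend
father
power
hour
game
line
end
member
law
car
city
community
name
president
team
minute
idea
body
information
nothing
ago
face
others
level
office
door
health
person
art
war
history
party
result
morning
reason
research
girl
guy
moment
air
teacher
force
education
foot
boy
age
policy
everything
process
music
market
sense
nation
plan
college
interest
death
experience
effect
class
control
care
field
development
role
student
group
country
problem
hand
part
place
case
week
company
system
program
question
government
number
night
point
world
school
state
family
life
child
days
eyes
men
women
man
woman
something
anything
table
paper
street
light
heart
food
practice
piece
front
mind
view
message
truth
road
value
wife
season
hair
fire
space
town
ground
letter
hope
news
test
board
cost
west
north
south
east
building
dog
bird
animal
tree
fish
river
mountain
rain
snow
wind
sun
moon
star
sea
ocean
beach
rock
sand
grass
flower
leaf
branch
root
seed
fruit
apple
bread
milk
egg
meat
rice
salt
sugar
coffee
tea
wine
beer
glass
cup
plate
knife
fork
spoon
chair
bed
window
wall
floor
roof
kitchen
garden
yard
fence
gate
key
lock
box
bag
clothes
shirt
shoes
hat
coat
dress
pocket
button
color
red
blue
green
yellow
black
white
brown
gray
pink
purple
orange
big
small
long
short
tall
wide
narrow
deep
high
low
fast
slow
hot
cold
warm
cool
dry
wet
hard
soft
heavy
strong
weak
old
young
early
late
near
far
close
full
empty
clean
dirty
easy
difficult
simple
rich
poor
happy
sad
angry
afraid
tired
hungry
thirsty
sick
healthy
safe
dangerous
quiet
loud
bright
dark
beautiful
ugly
nice
mean
funny
serious
important
possible
impossible
real
true
false
wrong
correct
same
different
free
busy
ready
sure
certain
clear
whole
half
quarter
single
double
few
many
much
little
more
less
least
very
too
quite
rather
almost
always
usually
often
sometimes
rarely
never
again
once
twice
soon
already
yet
still
ever
together
alone
around
between
among
under
above
below
behind
beside
against
through
during
before
until
since
while
where
here
everywhere
somewhere
nowhere
today
tomorrow
yesterday
thes
thed
thing
ands
anded
anding
thats
thated
thating
haves
haved
having
fors
fored
foring
nots
noted
noting
withs
withed
withing
yous
youed
youing
thiss
thised
thising
buts
buted
buting
hiss
hised
hising
froms
fromed
froming
theys
theyed
theying
says
sayed
saying
hers
hered
hering
shes
shed
shing
wills
willed
willing
ones
oned
oning
alls
alled
alling
woulds
woulded
woulding
theres
thered
thering
theirs
theired
theiring
whats
whated
whating
outs
outed
outing
abouts
abouted
abouting
whos
whoed
whoing
gets
geted
geting
whichs
whiched
whiching
whens
whened
whening
makes
maked
making
cans
caned
caning
likes
liked
liking
times
timed
timing
justs
justed
justing
hims
himed
himing
knows
knowed
knowing
takes
taked
taking
peoples
peopled
peopling
intos
intoed
intoing
years
yeared
yearing
yours
youred
youring
goods
gooded
gooding
somes
somed
soming
coulds
coulded
coulding
thems
themed
theming
sees
seing
othered
othering
thans
thaned
thaning
thens
thened
thening
nows
nowed
nowing
looks
looking
onlys
onlyed
onlying
comes
comed
coming
itss
itsed
itsing
overs
overed
overing
thinks
thinked
thinking
alsos
alsoed
alsoing
backs
backed
backing
afters
aftered
aftering
uses
using
twos
twoed
twoing
hows
howed
howing
ours
oured
ouring
works
worked
working
firsts
firsted
firsting
wells
welled
welling
ways
wayed
waying
evens
evened
evening
newed
newing
wants
wanting
becauses
becaused
becausing
anys
anyed
anying
theses
thesed
thesing
gives
gived
giving
dayed
daying
mosts
mosted
mosting
wass
wased
wasing
ares
ared
aring
weres
wered
wering
beens
beened
beening
hass
hased
hasing
hads
haded
hading
dids
dided
diding
saids
saided
saiding
doings
doinged
doinging
beings
beinged
beinging
goess
goesed
goesing
gones
goned
goning
mades
maded
mading
knews
knewed
knewing
thoughts
thoughted
thoughting
lookeds
lookeded
lookeding
wanteds
wanteded
wanteding
gaves
gaved
gaving
useds
useded
useding
founds
founded
founding
tolds
tolded
tolding
askeds
askeded
askeding
seemeds
seemeded
seemeding
felts
felted
felting
lefts
lefted
lefting
puts
puted
puting
meants
meanted
meanting
kepts
kepted
kepting
lets
leted
leting
begans
beganed
beganing
seems
seeming
helps
helped
helping
talks
talked
talking
turns
turned
turning
starts
started
starting
mights
mighted
mighting
shows
showed
showing
hears
heared
hearing
plays
played
playing
runs
runed
runing
moves
moved
moving
lives
lived
living
believes
believed
believing
holds
holded
holding
brings
bringed
bringing
happens
happened
happening
writes
writed
writing
provides
provided
providing
sits
sited
siting
stands
standed
standing
loses
losed
losing
pays
payed
paying
meets
meeted
meeting
includes
included
including
continues
continued
continuing
sets
seted
seting
learns
learned
learning
changes
changed
changing
leads
leaded
leading
understands
understanded
understanding
watchs
watched
watching
follows
followed
following
stops
stoped
stoping
creates
created
creating
speaks
speaked
speaking
reads
readed
reading
allows
allowed
allowing
adds
added
adding
spends
spended
spending
grows
growed
growing
opens
opened
opening
walks
walked
walking
wins
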
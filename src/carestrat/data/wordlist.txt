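ability
about
access
accuracy
activity
affirmation
after
again
all
allow
along
already
also
always
an
and
animal
answer
anxiety
any
anything
applicable
are
area
around
arrangement
art
as
ask
at
attempt
awareness
away
back
bad
bag
balance
ball
barrier
be
because
bed
been
before
begin
behind
belief
believe
best
better
beyond
big
bike
blank
body
book
box
boy
break
breakdown
breakfast
breathe
bring
brother
build
bus
busy
but
buy
by
calendar
call
calm
came
can
car
card
care
carry
cat
catch
chair
challenge
change
character
chart
check
checklist
child
children
choice
choose
church
city
class
classroom
clean
clear
close
club
coach
color
come
comfort
comment
competence
computer
confidence
cool
coordination
corner
correction
could
courage
craft
cue
currently
daily
dance
day
decide
demonstrate
desire
desk
different
difficulty
dinner
discuss
distraction
do
does
dog
done
door
down
draw
dress
drill
drink
drum
each
early
easy
eat
effort
else
emotion
empathy
empty
encourage
end
endurance
enjoy
enjoyment
enough
environment
equipment
esteem
even
evening
ever
every
exercise
explain
extra
face
fact
fall
family
far
fast
father
favorite
feedback
feel
feet
felt
find
fine
finish
first
floor
follow
food
foot
for
forget
found
four
friend
from
front
full
fun
furniture
game
garden
gave
get
girl
give
go
goal
going
good
got
great
group
grow
guide
hand
happy
hard
have
he
head
headphone
hear
heard
heart
help
her
here
high
his
hobby
hold
home
homework
hope
hour
house
how
i
idea
identity
important
improve
independence
instruction
interest
into
involve
involved
is
issue
it
its
join
journal
jump
just
keep
kind
kindness
knew
know
label
large
last
late
layout
learn
leave
left
lesson
let
letter
level
life
light
like
line
list
listen
little
live
long
look
loud
love
made
make
man
many
master
maturity
may
maybe
mean
meet
memory
men
menu
might
milestone
mind
mindset
minute
miss
model
mom
moment
money
month
mood
morning
mother
motivation
motivator
move
movie
much
music
must
my
na
name
near
need
needed
neighbor
never
new
news
next
nice
night
no
nobody
noise
none
nope
not
note
nothing
now
number
often
okay
old
once
one
only
open
opinion
option
other
our
over
own
ownership
page
paper
parent
park
part
passion
patience
peace
people
perhaps
person
phone
piano
pick
picture
place
plan
play
playground
please
point
pool
positive
practice
praise
preference
prepare
pretty
pride
problem
progress
proud
put
question
quick
quickly
quiet
rail
ramp
rarely
read
ready
real
really
reassure
reflection
relax
remember
remind
reminder
repeat
resilience
response
responsibility
rest
review
reward
right
room
routine
run
safe
said
same
saw
say
schedule
school
seat
see
seem
select
sequence
set
share
she
short
should
show
side
sign
simple
since
sing
sister
sit
situation
skill
skip
sleep
slowly
small
smile
snack
so
soft
some
sometimes
song
soon
sound
space
speak
speed
spell
sport
stand
start
stay
step
still
stop
store
story
strategies
strength
stress
structure
student
study
style
such
support
sure
table
tablet
take
talk
task
taste
teach
teacher
team
technique
tell
than
thank
that
the
their
them
theme
then
there
these
they
thing
think
this
those
thought
three
through
time
timer
today
together
told
too
took
tool
tooth
topic
toy
train
transport
trip
trust
try
turn
tutor
two
unclear
under
unknown
unsure
until
upon
use
used
variety
very
video
visit
visual
voice
vote
wait
wake
walk
wall
want
warm
was
wash
watch
water
way
we
week
weekly
well
went
were
what
when
where
which
while
white
who
whole
why
will
window
wish
with
without
woman
word
work
world
worth
would
write
yard
year
yes
yet
young
your
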